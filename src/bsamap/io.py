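"""Tabular I/O for the pipeline: bulk allele-count tables, genome layouts,
and BED region output.  Parsing and validation only — no statistics.

The canonical interchange format is an 8-column TSV with header
``chrom pos ref alt refA altA refB altB``: one row per biallelic SNP, with
read counts for the reference and alternate allele in bulk A (the
mutant-phenotype bulk) and bulk B (the wild-phenotype bulk).  A VCF reader
is provided as a convenience for tables produced by standard variant
callers; it consumes per-sample allele depths (FORMAT/AD) from exactly two
samples and requires an explicit sample -> bulk mapping, because the sign
of Delta(SNP-index) depends on which bulk is which.

All internal coordinates are 1-based inclusive.  Only BED output is 0-based
half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["chrom", "pos", "ref", "alt", "refA", "altA", "refB", "altB"]
_COUNT_FIELDS = ["refA", "altA", "refB", "altB"]


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


class ValidationError(ValueError):
    """A file parses but violates a table invariant (e.g. negative count)."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp) for window placement.

    Parameters
    ----------
    chroms : sequence of (name, length) pairs
        Lengths are 1-based inclusive extents; must be positive and names
        unique.
    """

    chroms: tuple[tuple[str, int], ...] = field(default_factory=tuple)

    def __init__(self, chroms: Iterable[tuple[str, int]]):
        chroms = tuple((str(c), int(n)) for c, n in chroms)
        names = [c for c, _ in chroms]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in genome layout")
        for c, n in chroms:
            if n <= 0:
                raise ValidationError(f"chromosome {c!r} has non-positive length {n}")
        object.__setattr__(self, "chroms", chroms)

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chroms]

    def length(self, chrom: str) -> int:
        for c, n in self.chroms:
            if c == chrom:
                return n
        raise KeyError(f"unknown chromosome {chrom!r}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    def __iter__(self):
        return iter(self.chroms)


def read_genome(path: str | Path) -> GenomeLayout:
    """Read a two-column TSV (chrom, length) into a :class:`GenomeLayout`."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["chrom", "length"])
    if df.empty:
        raise FormatError(f"{path}: empty genome file")
    try:
        lengths = df["length"].astype(int)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-integer chromosome length") from exc
    return GenomeLayout(zip(df["chrom"].astype(str), lengths))


def _validate_counts(df: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing column(s) {', '.join(missing)}")
    df = df[COUNT_COLUMNS].copy()
    for col in ["pos", *_COUNT_FIELDS]:
        try:
            df[col] = df[col].astype(np.int64)
        except (ValueError, TypeError) as exc:
            first_bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            line = int(first_bad[0]) + 2 if len(first_bad) else "?"
            raise FormatError(f"{source}: non-integer value in column {col!r} (line {line})") from exc
    for col in _COUNT_FIELDS:
        bad = df.index[df[col] < 0]
        if len(bad):
            raise ValidationError(
                f"{source}: negative count in column {col!r} (line {int(bad[0]) + 2})"
            )
    bad = df.index[df["pos"] <= 0]
    if len(bad):
        raise ValidationError(f"{source}: non-positive position (line {int(bad[0]) + 2})")
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(f"{source}: duplicate site {row['chrom']}:{row['pos']}")
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return df


def read_bulk_counts(
    path: str | Path,
    dialect: str = "tsv",
    *,
    bulk_a_sample: str | None = None,
    bulk_b_sample: str | None = None,
    swap_alleles: bool = False,
) -> pd.DataFrame:
    """Read a bulk allele-count table.

    Parameters
    ----------
    path : path
        TSV file with the canonical 8 columns, or a VCF (dialect="vcf").
    dialect : {"tsv", "vcf"}
    bulk_a_sample, bulk_b_sample : str
        Required for VCF input: which sample is the mutant-phenotype bulk
        (A) and which the wild-phenotype bulk (B).  Never inferred — the
        sign of Delta(SNP-index) depends on it.
    swap_alleles : bool
        Exchange ref<->alt counts in both bulks, for tables coded with the
        mutant allele as reference.

    Returns
    -------
    DataFrame with columns chrom, pos, ref, alt, refA, altA, refB, altB,
    sorted by (chrom, pos).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
        df = _validate_counts(df, str(path))
    elif dialect == "vcf":
        df = _read_vcf_counts(path, bulk_a_sample, bulk_b_sample)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if swap_alleles:
        df[["refA", "altA", "refB", "altB"]] = df[["altA", "refA", "altB", "refB"]].to_numpy()
    return df


def _read_vcf_counts(path: Path, bulk_a: str | None, bulk_b: str | None) -> pd.DataFrame:
    from cyvcf2 import VCF

    if bulk_a is None or bulk_b is None:
        raise ValueError("VCF input requires explicit bulk_a_sample and bulk_b_sample")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(samples) != 2:
        raise FormatError(f"{path}: expected exactly 2 samples, found {len(samples)}")
    for name in (bulk_a, bulk_b):
        if name not in samples:
            raise FormatError(f"{path}: sample {name!r} not in VCF ({samples})")
    ia, ib = samples.index(bulk_a), samples.index(bulk_b)
    rows = []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1  # multi-allelic or indel
            continue
        ad = v.format("AD")
        if ad is None:
            raise FormatError(f"{path}: site {v.CHROM}:{v.POS} lacks FORMAT/AD")
        rows.append(
            (v.CHROM, v.POS, v.REF, v.ALT[0],
             int(ad[ia][0]), int(ad[ia][1]), int(ad[ib][0]), int(ad[ib][1]))
        )
    if n_skipped:
        logger.info("skipped %d multi-allelic/indel site(s) in %s", n_skipped, path)
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    return _validate_counts(df, str(path))


def write_bulk_counts(df: pd.DataFrame, path: str | Path, *, provenance: str | None = None) -> None:
    """Write a count table as canonical TSV (round-trips bit-exactly)."""
    path = Path(path)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index=False, columns=COUNT_COLUMNS)


def regions_to_bed(regions: Iterable[Sequence]) -> list[tuple[str, int, int, float]]:
    """Convert internal 1-based inclusive (chrom, start, end, score) regions
    to BED 0-based half-open tuples."""
    return [(str(c), int(s) - 1, int(e), float(x)) for c, s, e, x in regions]


def write_regions(regions: Iterable[Sequence], path: str | Path) -> None:
    """Write (chrom, start, end, score) tuples as a BED4 file.

    Coordinates are taken as already 0-based half-open (use
    :func:`regions_to_bed` to convert from the internal 1-based inclusive
    convention).  Unsorted input is sorted on write with a log note; an
    empty collection yields an empty file.
    """
    rows = [(str(c), int(s), int(e), x) for c, s, e, x in regions]
    for c, s, e, _ in rows:
        if not s < e:
            raise ValidationError(f"region {c}:{s}-{e}: start must be < end")
    if rows != sorted(rows, key=lambda r: (r[0], r[1], r[2])):
        logger.info("write_regions: input not sorted; sorting on write")
        rows = sorted(rows, key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for c, s, e, x in rows:
            fh.write(f"{c}\t{s}\t{e}\t{x:g}\n")


def read_regions(path: str | Path) -> list[tuple[str, int, int, float]]:
    """Read a BED4 file back into 0-based half-open tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: expected 4 BED columns, got {len(parts)}")
            out.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
    return out
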