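"""Recombinant-driven fine mapping of a recessive locus.

Mutant-phenotype plants from a segregating population are homozygous for
the mutant allele (``B``) at the causal locus, so every informative
recombinant narrows the candidate interval: a non-``B`` call (``A``
homozygous reference, or ``H`` heterozygous) at a marker excludes the
locus from that side of the nearest crossover.

For each mutant plant the compatible region is the union of maximal runs
of consecutive markers whose calls are all ``B`` or missing (and contain
at least one observed ``B``), each run widened to the open interval
bounded by the nearest flanking non-``B`` markers (or the chromosome
ends).  The candidate region is the intersection of all plants'
compatible regions.  When the intersection leaves several disjoint
intervals, the reported one is the interval anchored by the most markers
that are ``B`` in every plant (ties: the widest); all surviving
intervals are retained on the result.  Bounds are reported as the
positions of the flanking markers — the locus lies strictly between them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = "-"
CODES = {"A", "H", "B", MISSING}


class ConflictError(ValueError):
    """No genomic position is compatible with every mutant plant."""


@dataclass(frozen=True)
class RecombinantTable:
    """Ordered markers x plants genotype matrix with phenotypes.

    Parameters
    ----------
    markers : sequence of (name, chrom, pos)
        All on one chromosome, positions strictly increasing.
    plants : sequence of (id, phenotype, calls)
        phenotype in {"mutant", "wild"}; calls is one code per marker from
        {"A", "H", "B", "-"} ("-" = missing).
    """

    markers: tuple[tuple[str, str, int], ...]
    plants: tuple[tuple[str, str, tuple[str, ...]], ...]

    def __init__(self, markers, plants):
        markers = tuple((str(n), str(c), int(p)) for n, c, p in markers)
        if not markers:
            raise ValueError("need at least one marker")
        chroms = {c for _, c, _ in markers}
        if len(chroms) != 1:
            raise ValueError(f"markers span multiple chromosomes: {sorted(chroms)}")
        pos = [p for _, _, p in markers]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("marker positions must be strictly increasing")
        norm_plants = []
        for pid, pheno, calls in plants:
            if pheno not in ("mutant", "wild"):
                raise ValueError(f"plant {pid}: phenotype must be 'mutant' or 'wild'")
            calls = tuple(str(c) for c in calls)
            if len(calls) != len(markers):
                raise ValueError(f"plant {pid}: {len(calls)} calls for {len(markers)} markers")
            bad = set(calls) - CODES
            if bad:
                raise ValueError(f"plant {pid}: unknown genotype code(s) {sorted(bad)}")
            norm_plants.append((str(pid), pheno, calls))
        object.__setattr__(self, "markers", markers)
        object.__setattr__(self, "plants", tuple(norm_plants))

    @property
    def chrom(self) -> str:
        return self.markers[0][1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([p for _, _, p in self.markers])

    @classmethod
    def from_frames(cls, markers: pd.DataFrame, genotypes: pd.DataFrame) -> "RecombinantTable":
        """Build from a marker table (name, chrom, pos) and a genotype table
        (plant, phenotype, one column per marker name)."""
        marker_rows = list(zip(markers["name"], markers["chrom"], markers["pos"]))
        names = [n for n, _, _ in marker_rows]
        missing_cols = [n for n in names if n not in genotypes.columns]
        if missing_cols:
            raise ValueError(f"genotype table lacks marker column(s) {missing_cols}")
        plants = [
            (row["plant"], row["phenotype"], tuple(row[n] for n in names))
            for _, row in genotypes.iterrows()
        ]
        return cls(marker_rows, plants)


@dataclass(frozen=True)
class FineMapResult:
    """Narrowed candidate interval for the causal locus.

    ``left``/``right`` are the flanking marker positions (None = no
    recombinant on that side, i.e. the chromosome end); the locus lies
    strictly between them.  ``supporting`` lists the recombinant plants
    whose non-B calls define the bounds.  ``intervals`` holds every
    surviving open interval when the intersection is not a single run.
    """

    chrom: str
    left: int | None
    right: int | None
    supporting: tuple[str, ...]
    intervals: tuple[tuple[int | None, int | None], ...]
    n_plants_used: int
    excluded: tuple[str, ...] = ()

    def to_bed_row(self, chrom_length: int | None = None) -> tuple[str, int, int, float]:
        """Close the open interval onto the flanking marker coordinates
        (0-based half-open) for BED export."""
        left = 1 if self.left is None else self.left
        right = self.right
        if right is None:
            if chrom_length is None:
                raise ValueError("right bound is the chromosome end; pass chrom_length")
            right = chrom_length
        return (self.chrom, left - 1, right, 0.0)


def _compatible_intervals(
    calls: Sequence[str], pos: np.ndarray, strict_missing: bool
) -> list[tuple[float, float]]:
    """Open intervals compatible with the plant being homozygous mutant.

    Each maximal run of consecutive {B, missing} calls containing at
    least one observed B is widened to the open interval bounded by the
    nearest flanking non-B marker positions (chromosome ends -> +-inf).
    """
    ok = [c == "B" or (not strict_missing and c == MISSING) for c in calls]
    is_b = [c == "B" for c in calls]
    out: list[tuple[float, float]] = []
    i = 0
    while i < len(calls):
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < len(calls) and ok[j]:
            j += 1
        if any(is_b[i:j]):
            left = float(pos[i - 1]) if i > 0 else -np.inf
            right = float(pos[j]) if j < len(calls) else np.inf
            out.append((left, right))
        i = j
    return out


def _intersect(
    a: list[tuple[float, float]], b: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Intersection of two unions of disjoint open intervals."""
    out = []
    for la, ra in a:
        for lb, rb in b:
            lo, hi = max(la, lb), min(ra, rb)
            if lo < hi:
                out.append((lo, hi))
    return sorted(out)


def narrow_interval(
    table: RecombinantTable,
    *,
    strict_missing: bool = False,
    check_wild: bool = False,
    on_conflict: str = "raise",
) -> FineMapResult:
    """Intersect the compatible regions of all mutant plants.

    Parameters
    ----------
    table : RecombinantTable
    strict_missing : treat missing calls as breaking a run instead of as
        compatible-with-B (default off: untyped markers are non-informative).
    check_wild : advisory consistency check of wild-phenotype plants (they
        must not be B at every marker of the final interval); off by default.
    on_conflict : {"raise", "drop"}
        What to do with a plant whose genotypes are incompatible with every
        position of the running intersection (apparent double recombinant or
        phenotyping error): raise a :class:`ConflictError` (default), or
        drop the plant with a warning — useful for sparse marker panels over
        wide regions, where genuine double crossovers between distant
        markers are expected.

    Raises
    ------
    ConflictError
        When the intersection empties and ``on_conflict="raise"``.
    """
    if on_conflict not in ("raise", "drop"):
        raise ValueError("on_conflict must be 'raise' or 'drop'")
    pos = table.positions
    mutants = [(pid, calls) for pid, ph, calls in table.plants if ph == "mutant"]
    excluded = [pid for pid, calls in mutants if "B" not in calls]
    if excluded:
        logger.warning("excluding plant(s) with no B call at any marker: %s", excluded)
        mutants = [(pid, calls) for pid, calls in mutants if "B" in calls]
    if not mutants:
        raise ValueError("no usable mutant-phenotype plants")

    region = [(-np.inf, np.inf)]
    used: list[tuple[str, tuple[str, ...]]] = []
    dropped: list[str] = []
    for pid, calls in mutants:
        nxt = _intersect(region, _compatible_intervals(calls, pos, strict_missing))
        if not nxt:
            if on_conflict == "raise":
                raise ConflictError(
                    f"compatible region became empty at plant {pid} (double "
                    "recombinant or phenotyping error); plants intersected so far: "
                    + ", ".join([p for p, _ in used] + [pid])
                )
            logger.warning("dropping conflicting plant %s (incompatible with running "
                           "intersection)", pid)
            dropped.append(pid)
            continue
        region = nxt
        used.append((pid, calls))
    mutants = used
    excluded = excluded + dropped

    # prefer the interval anchored by markers that are B in every plant
    all_b = np.array([all(calls[k] == "B" for _, calls in mutants) for k in range(len(pos))])

    def score(iv):
        lo, hi = iv
        inside = (pos > lo) & (pos < hi)
        return (int(all_b[inside].sum()), hi - lo)

    best = max(region, key=score)
    left = None if np.isneginf(best[0]) else int(best[0])
    right = None if np.isposinf(best[1]) else int(best[1])
    intervals = tuple(
        (None if np.isneginf(lo) else int(lo), None if np.isposinf(hi) else int(hi))
        for lo, hi in region
    )

    supporting = []
    pos_list = list(pos)
    for pid, calls in mutants:
        sets_left = left is not None and calls[pos_list.index(left)] in ("A", "H")
        sets_right = right is not None and calls[pos_list.index(right)] in ("A", "H")
        if sets_left or sets_right:
            supporting.append(pid)

    if check_wild:
        inside = [k for k in range(len(pos)) if (left is None or pos[k] > left)
                  and (right is None or pos[k] < right)]
        for pid, ph, calls in table.plants:
            if ph == "wild" and inside and all(calls[k] == "B" for k in inside):
                logger.warning(
                    "wild plant %s is B across the candidate interval (possible "
                    "phenotyping error)", pid
                )

    return FineMapResult(
        chrom=table.chrom,
        left=left,
        right=right,
        supporting=tuple(supporting),
        intervals=intervals,
        n_plants_used=len(mutants),
        excluded=tuple(excluded),
    )
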