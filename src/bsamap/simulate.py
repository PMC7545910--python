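"""Forward simulator for single-locus mapping populations and pooled reads.

Emulates the study design behind a bulked-segregant experiment: an F2 (or
BC1-to-mutant) population segregating one fully recessive locus, phenotype
selection of two bulks (default 21 plants each, from a 185-plant F2), and
short-read allele sampling at SNP positions with Poisson depth and a small
per-read error rate.

Genetics model
--------------
Two fully inbred parents differ at every simulated SNP; allele ``B`` is the
mutant-parent allele, ``A`` the reference-parent allele.  F1 gametes are
generated by a Markov walk along the ordered loci of each chromosome:
crossover between adjacent loci occurs with probability given by Haldane's
map function r = (1 - exp(-2 d / 100)) / 2 where d is the genetic distance
in centimorgans, obtained from physical distance via a constant cM/Mb
scaling (no crossover interference).  An F2 plant is the fusion of two
independent F1 gametes; a BC1-to-mutant plant is one F1 gamete plus an
all-``B`` gamete.  Phenotype is ``mutant`` iff the plant is BB at the
causal locus (full penetrance by default; a misphenotyping probability is
available for robustness studies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from bsamap.io import COUNT_COLUMNS, GenomeLayout

logger = logging.getLogger(__name__)

F2 = "F2"
BC1 = "BC1_to_mutant"
CROSS_TYPES = (F2, BC1)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated mapping experiment.

    Defaults mirror the emulated study design: 185 F2 plants, bulks of 21,
    one SNP every 50 kb, Poisson mean depth 30 per SNP per bulk, per-read
    error 1e-3, and a genome-wide map scale of 3 cM/Mb.
    """

    genome: GenomeLayout
    causal_chrom: str
    causal_pos: int
    cross_type: str = F2
    n_plants: int = 185
    bulk_size: int = 21
    snp_spacing: int = 50_000
    snp_positions: dict[str, Sequence[int]] | None = None
    cm_per_mb: float = 3.0
    mean_depth: float = 30.0
    error_rate: float = 0.001
    misphenotype_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.cross_type not in CROSS_TYPES:
            raise ConfigError(f"cross_type must be one of {CROSS_TYPES}")
        if self.causal_chrom not in self.genome:
            raise ConfigError(f"causal chromosome {self.causal_chrom!r} not in genome")
        if not 1 <= self.causal_pos <= self.genome.length(self.causal_chrom):
            raise ConfigError(
                f"causal position {self.causal_pos} outside chromosome "
                f"{self.causal_chrom} (1..{self.genome.length(self.causal_chrom)})"
            )
        if self.cm_per_mb <= 0:
            raise ConfigError("cm_per_mb must be > 0")
        if not 0 <= self.error_rate < 0.5:
            raise ConfigError("error_rate must be in [0, 0.5)")
        if not 0 <= self.misphenotype_rate < 1:
            raise ConfigError("misphenotype_rate must be in [0, 1)")
        if self.n_plants < 1:
            raise ConfigError("n_plants must be >= 1")

    def loci(self) -> pd.DataFrame:
        """Ordered (chrom, pos) marker table, causal locus always included."""
        rows = []
        for chrom, length in self.genome:
            if self.snp_positions is not None:
                pos = sorted(int(p) for p in self.snp_positions.get(chrom, ()))
            else:
                pos = list(range(self.snp_spacing, length + 1, self.snp_spacing))
            if chrom == self.causal_chrom and self.causal_pos not in pos:
                pos = sorted(pos + [self.causal_pos])
            rows.extend((chrom, p) for p in pos)
        df = pd.DataFrame(rows, columns=["chrom", "pos"])
        df["is_causal"] = (df["chrom"] == self.causal_chrom) & (df["pos"] == self.causal_pos)
        return df


@dataclass
class SimPopulation:
    """Realized genotypes and phenotypes of a simulated population.

    Attributes
    ----------
    loci : DataFrame (chrom, pos, is_causal), one row per marker.
    dosage : int8 array (n_plants, n_loci)
        Count of mutant (``B``) alleles per plant per locus: 0=AA, 1=AB, 2=BB.
    phenotype : array of {"mutant", "wild"} per plant.
    config : the generating :class:`SimConfig`.
    """

    loci: pd.DataFrame
    dosage: np.ndarray
    phenotype: np.ndarray
    config: SimConfig

    @property
    def n_plants(self) -> int:
        return self.dosage.shape[0]

    @property
    def causal_index(self) -> int:
        return int(np.flatnonzero(self.loci["is_causal"].to_numpy())[0])

    def genotype_codes(self) -> np.ndarray:
        """Dosage matrix recoded as {"A", "H", "B"} strings."""
        return np.array(["A", "H", "B"])[self.dosage]


def haldane_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function: recombination fraction for d centimorgans."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def _gametes(rng: np.random.Generator, n: int, loci: pd.DataFrame, cm_per_mb: float) -> np.ndarray:
    """n F1 gametes over all loci: 0 = A allele, 1 = B allele."""
    out = np.empty((n, len(loci)), dtype=np.int8)
    for chrom, idx in loci.groupby("chrom", sort=False).indices.items():
        pos = loci["pos"].to_numpy()[idx]
        d_cm = np.diff(pos) / 1e6 * cm_per_mb
        r = haldane_r(d_cm)
        first = rng.integers(0, 2, size=(n, 1))
        if len(pos) > 1:
            # parental phase flips at every crossover: cumulative XOR walk
            cross = rng.random((n, len(pos) - 1)) < r
            alleles = (first + np.concatenate(
                [np.zeros((n, 1), dtype=np.int64), np.cumsum(cross, axis=1)], axis=1)) % 2
        else:
            alleles = first
        out[:, idx] = alleles.astype(np.int8)
    return out


def simulate_population(cfg: SimConfig) -> SimPopulation:
    """Simulate genotypes and phenotypes for one population.

    Reproducible: the same config (including seed) yields bit-identical
    genotype and phenotype arrays.
    """
    rng = np.random.default_rng(cfg.seed)
    loci = cfg.loci()
    n = cfg.n_plants
    if cfg.cross_type == F2:
        dosage = _gametes(rng, n, loci, cfg.cm_per_mb) + _gametes(rng, n, loci, cfg.cm_per_mb)
    else:  # BC1 to the mutant parent: one F1 gamete + an all-B gamete
        dosage = _gametes(rng, n, loci, cfg.cm_per_mb) + np.int8(1)
    causal = int(np.flatnonzero(loci["is_causal"].to_numpy())[0])
    mutant = dosage[:, causal] == 2
    if cfg.misphenotype_rate > 0:
        flip = rng.random(n) < cfg.misphenotype_rate
        mutant = mutant ^ flip
    phenotype = np.where(mutant, "mutant", "wild")
    return SimPopulation(loci=loci, dosage=dosage, phenotype=phenotype, config=cfg)


def build_bulks(
    pop: SimPopulation, bulk_size: int | None = None, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the two phenotype-selected bulks.

    Bulk A is a uniform random sample (without replacement) of
    mutant-phenotype plants, bulk B likewise of wild-phenotype plants; the
    bulks are disjoint by construction.  Returns (bulk_a_ids, bulk_b_ids)
    as sorted plant indices.
    """
    if bulk_size is None:
        bulk_size = pop.config.bulk_size
    if bulk_size < 0:
        raise ConfigError("bulk_size must be >= 0")
    rng = np.random.default_rng(pop.config.seed + 1 if seed is None else seed)
    mutants = np.flatnonzero(pop.phenotype == "mutant")
    wilds = np.flatnonzero(pop.phenotype == "wild")
    for name, ids in (("mutant", mutants), ("wild", wilds)):
        if len(ids) < bulk_size:
            raise ConfigError(
                f"cannot build bulk of {bulk_size}: only {len(ids)} {name}-phenotype "
                f"plants available (short by {bulk_size - len(ids)})"
            )
    bulk_a = np.sort(rng.choice(mutants, size=bulk_size, replace=False))
    bulk_b = np.sort(rng.choice(wilds, size=bulk_size, replace=False))
    return bulk_a, bulk_b


def sample_reads(
    pop: SimPopulation,
    bulks: tuple[np.ndarray, np.ndarray],
    cfg: SimConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample pooled short reads at every SNP for both bulks.

    For each SNP and bulk the true B-allele frequency is
    p = (sum of per-plant B dosages) / (2 * bulk size); read depth is
    Poisson(mean_depth) and the alternate-read count is
    Binomial(depth, p*(1-e) + (1-p)*e) with per-read error e.  Returns the
    canonical bulk count table (alt = B allele).
    """
    if cfg is None:
        cfg = pop.config
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    bulk_a, bulk_b = bulks
    n_loci = len(pop.loci)
    df = pop.loci[["chrom", "pos"]].copy()
    df["ref"], df["alt"] = "A", "T"
    e = cfg.error_rate
    for tag, ids in (("A", bulk_a), ("B", bulk_b)):
        if len(ids):
            p = pop.dosage[ids, :].sum(axis=0) / (2.0 * len(ids))
        else:
            p = np.zeros(n_loci)
        depth = rng.poisson(cfg.mean_depth, size=n_loci)
        p_read = p * (1 - e) + (1 - p) * e
        alt = rng.binomial(depth, p_read)
        df[f"ref{tag}"] = depth - alt
        df[f"alt{tag}"] = alt
    return df[COUNT_COLUMNS]


def simulate_experiment(cfg: SimConfig) -> tuple[pd.DataFrame, SimPopulation, tuple[np.ndarray, np.ndarray]]:
    """Convenience driver: population -> bulks -> pooled reads.

    Returns (counts table, population, (bulk_a, bulk_b)); all randomness is
    derived from cfg.seed.
    """
    pop = simulate_population(cfg)
    bulks = build_bulks(pop)
    counts = sample_reads(pop, bulks)
    return counts, pop, bulks


def truth_dict(pop: SimPopulation, bulks: tuple[np.ndarray, np.ndarray]) -> dict:
    """JSON-serializable ground truth for recovery tests."""
    cfg = pop.config
    return {
        "causal_chrom": cfg.causal_chrom,
        "causal_pos": int(cfg.causal_pos),
        "cross_type": cfg.cross_type,
        "seed": int(cfg.seed),
        "n_plants": int(cfg.n_plants),
        "bulk_a": [int(i) for i in bulks[0]],
        "bulk_b": [int(i) for i in bulks[1]],
        "n_mutant": int((pop.phenotype == "mutant").sum()),
        "n_wild": int((pop.phenotype == "wild").sum()),
    }
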