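"""Sliding-window genome scan, Monte-Carlo null confidence intervals, and
candidate-region calling.

Window averaging follows the QTL-seq convention: unweighted arithmetic
means of SNP-index and Delta(SNP-index) over all SNPs in each window
(default 1 Mb windows advanced in 10 kb steps, anchored at position 1).

Confidence intervals come from simulating Delta(SNP-index) under the
no-QTL null: both bulks are random draws from the segregating population
(F2 Hardy-Weinberg 1/4 : 1/2 : 1/4, or BC1-to-mutant 1/2 AB : 1/2 BB), so
any observed excess reflects linkage, not bulk construction.  Per-SNP
bounds are keyed by the smaller of the two bulk depths (conservative) and
then window-averaged alongside Delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bsamap.io import GenomeLayout
from bsamap.simulate import BC1, CROSS_TYPES, F2

CI_COLUMNS = ["ci95_lo", "ci95_hi", "ci99_lo", "ci99_hi"]


def _null_delta(
    rng: np.random.Generator, cross_type: str, bulk_size: int, depth: int, n: int
) -> np.ndarray:
    """n draws of Delta(SNP-index) under the no-QTL null at one depth."""
    deltas = np.empty(n)
    idx = []
    for _ in range(2):  # two bulks, independent
        # bulk B-allele dosage sum: F2 plants are Binomial(2, 1/2) so the
        # sum over the bulk is Binomial(2*bulk, 1/2); BC1-to-mutant plants
        # are 1 + Bernoulli(1/2).
        if cross_type == F2:
            total = rng.binomial(2 * bulk_size, 0.5, size=n)
        else:
            total = bulk_size + rng.binomial(bulk_size, 0.5, size=n)
        p = total / (2.0 * bulk_size)
        alt = rng.binomial(depth, p)
        idx.append(alt / depth)
    return idx[0] - idx[1]


@dataclass
class NullCiTable:
    """Quantiles of null Delta(SNP-index), per read depth.

    ``bounds[depth]`` holds (q2.5, q97.5, q0.5, q99.5) from
    ``n_replicates`` Monte-Carlo draws.  Missing depths are computed on
    demand (seeded deterministically from ``seed`` and the depth) and
    cached.
    """

    cross_type: str
    bulk_size: int
    n_replicates: int = 10_000
    seed: int = 0
    bounds: dict[int, tuple[float, float, float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.cross_type not in CROSS_TYPES:
            raise ValueError(f"cross_type must be one of {CROSS_TYPES}")
        if self.bulk_size < 1:
            raise ValueError("bulk_size must be >= 1")

    def for_depth(self, depth: int) -> tuple[float, float, float, float]:
        depth = int(depth)
        if depth < 1:
            raise ValueError("depth must be >= 1")
        if depth not in self.bounds:
            # derive a per-depth stream so the table is order-independent
            rng = np.random.default_rng((self.seed, depth))
            d = _null_delta(rng, self.cross_type, self.bulk_size, depth, self.n_replicates)
            q = np.quantile(d, [0.025, 0.975, 0.005, 0.995])
            self.bounds[depth] = (float(q[0]), float(q[1]), float(q[2]), float(q[3]))
        return self.bounds[depth]

    def null_draws(self, depth: int, n: int, seed: int = 1) -> np.ndarray:
        """Fresh null Delta draws (independent of the tabulated quantiles)."""
        rng = np.random.default_rng((self.seed, int(depth), seed))
        return _null_delta(rng, self.cross_type, self.bulk_size, int(depth), n)


def simulate_null_ci(
    cross_type: str,
    bulk_size: int,
    depths,
    n_replicates: int = 10_000,
    seed: int = 0,
) -> NullCiTable:
    """Tabulate 95% and 99% null bounds of Delta(SNP-index) for each depth."""
    table = NullCiTable(
        cross_type=cross_type, bulk_size=bulk_size, n_replicates=n_replicates, seed=seed
    )
    for d in depths:
        table.for_depth(int(d))
    return table


def attach_ci(index_table: pd.DataFrame, table: NullCiTable) -> pd.DataFrame:
    """Attach per-SNP null CI bounds, keyed by min(depthA, depthB).

    Depths absent from the table are computed on demand and cached, so any
    input table is covered.
    """
    out = index_table.copy()
    keys = np.minimum(out["depthA"].to_numpy(), out["depthB"].to_numpy())
    uniq = np.unique(keys)
    per_depth = {int(d): table.for_depth(int(d)) for d in uniq}
    stacked = np.array([per_depth[int(d)] for d in keys]) if len(keys) else np.empty((0, 4))
    for j, col in enumerate(CI_COLUMNS):
        out[col] = stacked[:, j] if len(keys) else np.array([])
    return out


def slide_windows(
    index_table: pd.DataFrame,
    genome: GenomeLayout,
    window_bp: int = 1_000_000,
    step_bp: int = 10_000,
) -> pd.DataFrame:
    """Sliding-window means of SNP-index, Delta, and (if attached) CI bounds.

    Windows start at 1, 1+step, ... on every chromosome of ``genome`` and
    span ``window_bp`` (truncated at the chromosome end).  Each window's
    statistics are unweighted means over SNPs with start <= pos <= end;
    empty windows are emitted with n_snps=0 and NaN means.
    """
    if window_bp < step_bp:
        raise ValueError("window_bp must be >= step_bp")
    unknown = set(index_table["chrom"].unique()) - set(genome.names)
    if unknown:
        raise ValueError(f"records on chromosome(s) {sorted(unknown)} not in genome layout")
    mean_cols = ["indexA", "indexB", "delta"] + [c for c in CI_COLUMNS if c in index_table.columns]
    frames = []
    for chrom, length in genome:
        sub = index_table[index_table["chrom"] == chrom].sort_values("pos")
        pos = sub["pos"].to_numpy()
        starts = np.arange(1, length + 1, step_bp, dtype=np.int64)
        ends = np.minimum(starts + window_bp - 1, length)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        n = (hi - lo).astype(np.int64)
        win = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "n_snps": n})
        for col in mean_cols:
            csum = np.concatenate([[0.0], np.cumsum(sub[col].to_numpy(dtype=float))])
            with np.errstate(invalid="ignore"):
                win["mean_" + col] = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
        frames.append(win)
    return pd.concat(frames, ignore_index=True)


def call_regions(
    windows: pd.DataFrame, level: int = 99, two_sided: bool = False
) -> pd.DataFrame:
    """Merge significant windows into candidate regions.

    A window is significant when its mean Delta exceeds the
    window-averaged upper null bound at the chosen level (one-sided high
    by default: bulk A carries the recessive phenotype so linkage pushes
    Delta positive).  Overlapping or bookended significant windows merge;
    each region reports the peak window's mean Delta and center position.

    Returns a DataFrame (chrom, start, end, peak_delta, peak_pos), empty
    when nothing exceeds the bounds.
    """
    if level not in (95, 99):
        raise ValueError("level must be 95 or 99")
    hi_col, lo_col = f"mean_ci{level}_hi", f"mean_ci{level}_lo"
    if hi_col not in windows.columns:
        raise ValueError(
            "windows carry no null CI bounds; run simulate_null_ci/attach_ci before scanning"
        )
    occupied = windows["n_snps"] > 0
    sig = occupied & (windows["mean_delta"] > windows[hi_col])
    if two_sided:
        sig = sig | (occupied & (windows["mean_delta"] < windows[lo_col]))
    regions = []
    for chrom, grp in windows[sig].groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cur = None
        for row in grp.itertuples():
            if cur is not None and row.start <= cur["end"] + 1:
                cur["end"] = max(cur["end"], row.end)
                cur["members"].append(row)
            else:
                if cur is not None:
                    regions.append(cur)
                cur = {"chrom": chrom, "start": row.start, "end": row.end, "members": [row]}
        if cur is not None:
            regions.append(cur)
    rows = []
    for reg in regions:
        peak = max(reg["members"], key=lambda r: r.mean_delta)
        rows.append(
            (reg["chrom"], int(reg["start"]), int(reg["end"]),
             float(peak.mean_delta), int((peak.start + peak.end) // 2))
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_delta", "peak_pos"])
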