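"""Per-SNP statistics: SNP-index per bulk, Delta(SNP-index), and the
depth/index filtering rules.

SNP-index at one position = alternate-read count / total aligned reads, per
bulk; Delta(SNP-index) = index(bulk A, mutant phenotype) - index(bulk B,
wild phenotype).  Near a recessive causal locus bulk A tends to index 1
(all selected plants homozygous mutant) and bulk B to 1/3 in an F2, so
Delta peaks at +2/3 under full linkage.

The default filter removes positions with read depth below 7 in *both*
bulks, or SNP-index below 0.3 in *either* bulk.  Both arms are
configurable ("both"/"either") because QTL-seq studies differ in how the
index rule is applied; the defaults follow the literal reading above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INDEX_COLUMNS = ["chrom", "pos", "depthA", "depthB", "indexA", "indexB", "delta"]


@dataclass(frozen=True)
class FilterPolicy:
    """SNP retention policy.

    A SNP is *removed* when the depth rule triggers or the index rule
    triggers.  With the defaults: depth rule = depth < 7 in both bulks;
    index rule = index < 0.3 in either bulk.
    """

    min_depth: int = 7
    min_index: float = 0.3
    depth_rule: str = "both"   # low depth must hold in {both, either} bulk(s)
    index_rule: str = "either"  # low index in {either, both} bulk(s) removes

    def __post_init__(self):
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if not 0 <= self.min_index <= 1:
            raise ValueError("min_index must be in [0, 1]")
        for name in ("depth_rule", "index_rule"):
            if getattr(self, name) not in ("both", "either"):
                raise ValueError(f"{name} must be 'both' or 'either'")


def compute_snp_index(counts: pd.DataFrame) -> pd.DataFrame:
    """Compute per-bulk SNP-index and Delta(SNP-index) for a count table.

    Positions with zero depth in either bulk are dropped (logged); the
    statistic is undefined there.  Returns a table with columns
    chrom, pos, depthA, depthB, indexA, indexB, delta.
    """
    out = counts[["chrom", "pos"]].copy()
    out["depthA"] = counts["refA"] + counts["altA"]
    out["depthB"] = counts["refB"] + counts["altB"]
    covered = (out["depthA"] > 0) & (out["depthB"] > 0)
    n_dropped = int((~covered).sum())
    if n_dropped:
        logger.info("compute_snp_index: dropped %d zero-depth position(s)", n_dropped)
    out = out[covered].copy()
    alt_a = counts.loc[covered, "altA"].to_numpy(dtype=float)
    alt_b = counts.loc[covered, "altB"].to_numpy(dtype=float)
    out["indexA"] = alt_a / out["depthA"].to_numpy()
    out["indexB"] = alt_b / out["depthB"].to_numpy()
    out["delta"] = out["indexA"] - out["indexB"]
    return out.reset_index(drop=True)


def apply_filters(index_table: pd.DataFrame, policy: FilterPolicy = FilterPolicy()) -> pd.DataFrame:
    """Apply the depth and index removal rules; order is preserved.

    Removal = (low depth per ``depth_rule``) OR (low index per
    ``index_rule``).  Per-rule removal counts are logged.
    """
    low_da = index_table["depthA"] < policy.min_depth
    low_db = index_table["depthB"] < policy.min_depth
    depth_bad = (low_da & low_db) if policy.depth_rule == "both" else (low_da | low_db)
    low_ia = index_table["indexA"] < policy.min_index
    low_ib = index_table["indexB"] < policy.min_index
    index_bad = (low_ia | low_ib) if policy.index_rule == "either" else (low_ia & low_ib)
    removed = depth_bad | index_bad
    if removed.any():
        logger.info(
            "apply_filters: removed %d/%d SNPs (depth rule %d, index rule %d)",
            int(removed.sum()), len(index_table), int(depth_bad.sum()), int(index_bad.sum()),
        )
    return index_table[~removed].copy()
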