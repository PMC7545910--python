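"""Arnon-type chlorophyll quantification from extract absorbances.

Chlorophyll a, chlorophyll b and total chlorophyll (mg per g fresh
weight) from absorbances at 663 and 645 nm, extraction volume V (mL) and
sample fresh weight W (g):

    Chla = (12.7 * OD663 - 2.69 * OD645) * V / (1000 * W)
    Chlb = (22.9 * OD645 - 4.68 * OD663) * V / (1000 * W)
    Chl  = (20.21 * OD645 + 8.02 * OD663) * V / (1000 * W)

The coefficient sets are mutually consistent (12.7 - 4.68 = 8.02 and
22.9 - 2.69 = 20.21), so Chl == Chla + Chlb identically.  Negative
outputs are returned but flagged — they indicate a physically impossible
absorbance pair, not an arithmetic problem.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def chlorophyll(od663, od645, volume_ml, weight_g, *, od633=None):
    """Chlorophyll a, b and total in mg per g fresh weight.

    Accepts scalars or array-likes (broadcast).  ``od633`` substitutes a
    separate 633-nm absorbance into the Chlb/Chl terms for replication of
    sources that print the formulas that way; by default the 663-nm
    reading is used throughout.

    Returns (chla, chlb, chl_total); emits a warning when any value is
    negative.
    """
    od663 = np.asarray(od663, dtype=float)
    od645 = np.asarray(od645, dtype=float)
    volume_ml = np.asarray(volume_ml, dtype=float)
    weight_g = np.asarray(weight_g, dtype=float)
    if np.any(od663 < 0) or np.any(od645 < 0):
        raise ValueError("absorbances must be >= 0")
    if np.any(volume_ml <= 0):
        raise ValueError("extraction volume must be > 0")
    if np.any(weight_g <= 0):
        raise ValueError("fresh weight must be > 0")
    od_b = od663 if od633 is None else np.asarray(od633, dtype=float)
    scale = volume_ml / (1000.0 * weight_g)
    chla = (12.7 * od663 - 2.69 * od645) * scale
    chlb = (22.9 * od645 - 4.68 * od_b) * scale
    chl = (20.21 * od645 + 8.02 * od_b) * scale
    if np.any(np.asarray(chla) < 0) or np.any(np.asarray(chlb) < 0):
        warnings.warn(
            "negative chlorophyll value: absorbance pair is outside the physical "
            "range of the equations", stacklevel=2
        )
    if np.ndim(chla) == 0:
        return float(chla), float(chlb), float(chl)
    return chla, chlb, chl


def chlorophyll_table(readings: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`chlorophyll` to a table with columns od663, od645,
    volume_ml, weight_g; returns the table with chla/chlb/chl appended."""
    required = ["od663", "od645", "volume_ml", "weight_g"]
    missing = [c for c in required if c not in readings.columns]
    if missing:
        raise ValueError(f"readings table lacks column(s) {missing}")
    chla, chlb, chl = chlorophyll(
        readings["od663"], readings["od645"], readings["volume_ml"], readings["weight_g"]
    )
    out = readings.copy()
    out["chla"], out["chlb"], out["chl"] = np.asarray(chla), np.asarray(chlb), np.asarray(chl)
    return out
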