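"""Chi-square goodness-of-fit tests for Mendelian segregation ratios.

For a monogenic recessive trait the F2 segregates 3 wild : 1 mutant and a
backcross to the recessive parent 1 : 1.  The test is the uncorrected
Pearson statistic against expected counts E_i = N * ratio_i / sum(ratio),
with df = classes - 1 and an upper-tail chi-square p-value; a Yates
continuity correction is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SegregationObservation:
    """Observed phenotype-class counts and the ratio they are tested against."""

    label: str
    observed: tuple[int, ...]
    expected_ratio: tuple[int, ...]

    def __post_init__(self):
        if len(self.observed) < 2:
            raise ValueError("need at least two phenotype classes")
        if len(self.observed) != len(self.expected_ratio):
            raise ValueError("observed and expected_ratio must have equal length")
        if any(o < 0 for o in self.observed):
            raise ValueError("observed counts must be >= 0")
        if any(r <= 0 for r in self.expected_ratio):
            raise ValueError("ratio terms must be > 0")
        if sum(self.observed) == 0:
            raise ValueError("total observed count must be > 0")


def chi_square_gof(
    obs: SegregationObservation | None = None,
    *,
    observed: Sequence[int] | None = None,
    ratio: Sequence[int] | None = None,
    yates: bool = False,
) -> tuple[float, int, float]:
    """Pearson goodness-of-fit test of counts against an integer ratio.

    Returns (chi2, df, p).  Either pass a :class:`SegregationObservation`
    or ``observed=`` and ``ratio=`` directly.

    Examples
    --------
    >>> chi2, df, p = chi_square_gof(observed=(143, 42), ratio=(3, 1))
    >>> round(chi2, 3), df, round(p, 3)
    (0.521, 1, 0.471)
    """
    if obs is None:
        obs = SegregationObservation("ad-hoc", tuple(observed), tuple(ratio))
    total = sum(obs.observed)
    rsum = sum(obs.expected_ratio)
    expected = [total * r / rsum for r in obs.expected_ratio]
    if any(e == 0 for e in expected):
        raise ValueError("expected count of zero")
    if yates:
        chi2 = sum((abs(o - e) - 0.5) ** 2 / e for o, e in zip(obs.observed, expected))
    else:
        chi2 = sum((o - e) ** 2 / e for o, e in zip(obs.observed, expected))
    df = len(obs.observed) - 1
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), df, p


def segregation_report(
    observations: Sequence[SegregationObservation], yates: bool = False
) -> pd.DataFrame:
    """Batch segregation report, one row per population.

    chi2 and p are rounded to 3 decimals in the formatted columns; the
    full-precision values are kept alongside.
    """
    rows = []
    for obs in observations:
        chi2, df, p = chi_square_gof(obs, yates=yates)
        rows.append(
            {
                "label": obs.label,
                "total": sum(obs.observed),
                "observed": ":".join(str(o) for o in obs.observed),
                "ratio": ":".join(str(r) for r in obs.expected_ratio),
                "chi2": chi2,
                "df": df,
                "p": p,
                "chi2_3dp": round(chi2, 3),
                "p_3dp": round(p, 3),
            }
        )
    return pd.DataFrame(rows)
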