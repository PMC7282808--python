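"""Population-level remapping profiles: evidence ratio -> Beta distribution.

A single evidence ratio summarizes the animal's belief, but place cells
respond heterogeneously.  The population is modelled by a Beta distribution
over per-cell rate-modulation extents r = 1 - (lower rate)/(higher rate) in
[0, 1] (0 = field unchanged, 1 = field appears/disappears).  The mapping
from an evidence ratio to Beta(a, b) puts the magnitude of the ratio plus
one on the parameter of the preferred hypothesis (b pulls mass toward 0 =
no remapping, a toward 1 = complete remapping), so ratio = b - a.

Thresholds at 0.15 and 0.85 partition the population into fractions that
do not remap, rate remap, and completely remap (closed-form Beta CDF).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

__all__ = ["RemapProfile", "evidence_to_beta", "remap_fractions", "heterogeneity_curve"]

DEFAULT_T_LOW = 0.15
DEFAULT_T_HIGH = 0.85


def evidence_to_beta(ratio: float) -> tuple[float, float]:
    """Map an evidence ratio to Beta shape parameters (a, b).

    A positive ratio prefers "no remapping" (mass toward 0): a = 1,
    b = ratio + 1.  A negative ratio prefers remapping: a = |ratio| + 1,
    b = 1.  The identity ratio = b - a holds in both branches.
    """
    if not np.isfinite(ratio):
        raise ValueError("evidence ratio must be finite")
    if ratio >= 0:
        return 1.0, float(ratio) + 1.0
    return float(-ratio) + 1.0, 1.0


def remap_fractions(
    a: float,
    b: float,
    t_low: float = DEFAULT_T_LOW,
    t_high: float = DEFAULT_T_HIGH,
) -> tuple[float, float, float]:
    """(no_remap, rate_remap, complete_remap) population fractions.

    no_remap = BetaCDF(t_low), complete_remap = 1 - BetaCDF(t_high),
    rate_remap = the remainder; the three sum to 1.
    """
    if a <= 0 or b <= 0:
        raise ValueError("Beta shape parameters must be positive")
    if not 0 < t_low < t_high < 1:
        raise ValueError("thresholds must satisfy 0 < t_low < t_high < 1")
    no_remap = float(beta_dist.cdf(t_low, a, b))
    complete = float(beta_dist.sf(t_high, a, b))
    return no_remap, 1.0 - no_remap - complete, complete


@dataclass(frozen=True)
class RemapProfile:
    """Beta population profile plus its derived remapping summaries."""

    a: float
    b: float
    t_low: float
    t_high: float
    fractions: tuple[float, float, float]
    mean_extent: float
    heterogeneity: float
    uncertainty: float

    @classmethod
    def from_evidence_ratio(
        cls,
        ratio: float,
        t_low: float = DEFAULT_T_LOW,
        t_high: float = DEFAULT_T_HIGH,
    ) -> "RemapProfile":
        a, b = evidence_to_beta(ratio)
        return cls(
            a=a,
            b=b,
            t_low=t_low,
            t_high=t_high,
            fractions=remap_fractions(a, b, t_low, t_high),
            mean_extent=float(beta_dist.mean(a, b)),
            heterogeneity=float(beta_dist.std(a, b)),
            uncertainty=float(np.exp(-abs(ratio))),
        )


def heterogeneity_curve(
    ratio_grid,
    t_low: float = DEFAULT_T_LOW,
    t_high: float = DEFAULT_T_HIGH,
) -> pd.DataFrame:
    """Population summaries across a grid of evidence ratios.

    Columns: ratio, a, b, mean_extent, complete_fraction (the extent of
    partial remapping: cells above t_high), heterogeneity (Beta standard
    deviation) and uncertainty (exp(-|ratio|)).
    """
    rows = []
    for ratio in np.asarray(ratio_grid, dtype=float):
        p = RemapProfile.from_evidence_ratio(ratio, t_low, t_high)
        rows.append(
            {
                "ratio": ratio,
                "a": p.a,
                "b": p.b,
                "mean_extent": p.mean_extent,
                "complete_fraction": p.fractions[2],
                "heterogeneity": p.heterogeneity,
                "uncertainty": p.uncertainty,
            }
        )
    return pd.DataFrame(rows)
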