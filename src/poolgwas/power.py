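"""Two-proportion power for unmatched case-control allelic effects.

Given a reference-group allele proportion ``p0`` and a per-allele odds ratio
``OR``, the comparison-group proportion is

    p1 = OR * p0 / (1 + p0 * (OR - 1)),

and the two-sided normal-approximation power at level ``alpha`` is

    power = Phi( |p1 - p0| / sqrt(p1 (1 - p1) / n_cases
                                  + p0 (1 - p0) / n_controls) - z_{1 - alpha/2} ).

The convention is per-subject (``n_cases`` and ``n_controls`` count people,
not alleles), matching standard unmatched case-control study power tools.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["cc_power", "power_grid"]


def cc_power(
    p0,
    odds_ratio,
    n_cases: int,
    n_controls: int,
    alpha: float = 0.05,
    continuity: bool = False,
):
    """Power to detect an allelic odds ratio in an unmatched design.

    Vectorised over ``p0`` and ``odds_ratio``.  ``continuity=True`` applies
    the standard continuity correction to the detectable difference.
    """
    p0 = np.asarray(p0, dtype=float)
    odds_ratio = np.asarray(odds_ratio, dtype=float)
    if np.any((p0 <= 0) | (p0 >= 1)):
        raise ValueError("p0 must lie in (0, 1)")
    if np.any(odds_ratio <= 0):
        raise ValueError("odds_ratio must be positive")
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("sample sizes must be positive")
    p1 = odds_ratio * p0 / (1.0 + p0 * (odds_ratio - 1.0))
    delta = np.abs(p1 - p0)
    if continuity:
        delta = np.maximum(delta - 0.5 * (1.0 / n_cases + 1.0 / n_controls), 0.0)
    se = np.sqrt(p1 * (1.0 - p1) / n_cases + p0 * (1.0 - p0) / n_controls)
    z = delta / se - stats.norm.ppf(1.0 - alpha / 2.0)
    out = stats.norm.cdf(z)
    return float(out) if out.ndim == 0 else out


def power_grid(
    n_cases: int,
    n_controls: int,
    p0_range: tuple[float, float] = (0.05, 0.5),
    or_range: tuple[float, float] = (1.2, 2.0),
    p0_step: float = 0.05,
    or_step: float = 0.1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Dense (p0 x OR) power grid as a tidy frame."""
    p0s = np.round(np.arange(p0_range[0], p0_range[1] + 1e-9, p0_step), 10)
    ors = np.round(np.arange(or_range[0], or_range[1] + 1e-9, or_step), 10)
    rows = []
    for p0 in p0s:
        for or_ in ors:
            rows.append(
                {
                    "p0": p0,
                    "odds_ratio": or_,
                    "n_cases": n_cases,
                    "n_controls": n_controls,
                    "alpha": alpha,
                    "power": cc_power(p0, or_, n_cases, n_controls, alpha),
                }
            )
    return pd.DataFrame(rows)
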