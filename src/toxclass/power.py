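"""Statistical power of the two-sided two-sample t-test.

The gradient feature selector weights each neighbor-class fold change by the
power a two-sample comparison of those classes would have at the observed
standardized effect size; this module provides that power, vectorized, via
the noncentral-t closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PowerSpec:
    """Parameters of the pairwise power computation.

    alpha
        Two-sided significance level of the underlying t-test.
    min_power
        Small floor applied to each pairwise power before the geometric
        mean, so a single near-zero power cannot annihilate the product.
    """

    alpha: float = 0.05
    min_power: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if not 0.0 < self.min_power <= 1.0:
            raise ValueError("min_power must lie in (0, 1]")


def power_of_two_sample_test(n1, n2, effect_size, alpha: float = 0.05):
    """Power of a two-sided pooled two-sample t-test.

    Parameters
    ----------
    n1, n2 : int or array of int
        Per-group sample sizes (each >= 2).
    effect_size : float or array
        Standardized mean difference (Cohen's d), >= 0. ``inf`` yields
        power 1; 0 yields power ``alpha``.
    alpha : float
        Two-sided significance level.

    Notes
    -----
    The test statistic under the alternative follows a noncentral t
    distribution with ``n1 + n2 - 2`` degrees of freedom and noncentrality
    ``d * sqrt(n1 n2 / (n1 + n2))``; power is the mass of that distribution
    beyond the two-sided critical values.
    """
    n1 = np.asarray(n1)
    n2 = np.asarray(n2)
    d = np.asarray(effect_size, dtype=float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("power requires at least 2 samples per group")
    if np.any(d < 0):
        raise ValueError("effect size must be non-negative")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")

    df = n1 + n2 - 2
    nc = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    with np.errstate(invalid="ignore", over="ignore"):
        upper = stats.nct.sf(tcrit, df, nc)
        lower = stats.nct.cdf(-tcrit, df, nc)
        # scipy's noncentral t overflows to NaN in the far tails at moderate
        # noncentrality; substitute the Gaussian limit there
        upper = np.where(np.isnan(upper), stats.norm.sf(tcrit - nc), upper)
        lower = np.where(np.isnan(lower), stats.norm.cdf(-tcrit - nc), lower)
        power = np.clip(upper + lower, 0.0, 1.0)
    # infinite effect sizes: the noncentral t mass is entirely beyond tcrit
    power = np.where(np.isinf(d), 1.0, power)
    return power if power.ndim else float(power)
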