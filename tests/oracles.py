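"""Independent reference implementations used only to check the package.

The gradient-score oracle below follows the published procedure literally,
step by step, with stdlib ``statistics`` primitives and statsmodels' power
solver — none of the package's vectorized code paths.
"""

from __future__ import annotations

import math
import statistics

import numpy as np
from scipy import stats
from statsmodels.stats.power import TTestIndPower

_POWER = TTestIndPower()


def oracle_power(n1: int, n2: int, d: float, alpha: float = 0.05) -> float:
    """Two-sided two-sample t-test power via statsmodels."""
    if d == 0:
        return alpha
    if math.isinf(d):
        return 1.0
    p = float(_POWER.power(effect_size=d, nobs1=n1, ratio=n2 / n1,
                           alpha=alpha, alternative="two-sided"))
    if math.isnan(p):
        # statsmodels' noncentral t overflows in the far tail; integrate
        # the mixture representation T = (Z + nc) / sqrt(V / df) directly
        from scipy import integrate

        df = n1 + n2 - 2
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        nc = d * math.sqrt(n1 * n2 / (n1 + n2))

        def tail(v, t):
            return stats.norm.cdf(nc - t * math.sqrt(v / df)) \
                * stats.chi2.pdf(v, df)

        upper, _ = integrate.quad(tail, 0, max(50 * df, 200), args=(tcrit,),
                                  limit=200)
        lower, _ = integrate.quad(
            lambda v: stats.norm.cdf(-nc - tcrit * math.sqrt(v / df))
            * stats.chi2.pdf(v, df), 0, max(50 * df, 200), limit=200)
        p = upper + lower
    return min(max(p, 0.0), 1.0)


def oracle_gradient_scores(X, y, alpha: float = 0.05,
                           min_power: float = 1e-6,
                           prefilter: bool = True) -> dict[int, float]:
    """Brute-force gradient R per surviving feature index.

    Steps, feature by feature: across-class Kruskal-Wallis filter; per-class
    medians; sort ascending; successive differences; pairwise power at the
    observed |median difference| / pooled SD; R = sample stdev of the
    differences times the geometric mean of the powers.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    out: dict[int, float] = {}
    for j in range(X.shape[1]):
        groups = [X[y == c, j].tolist() for c in classes]
        if prefilter:
            try:
                _, p = stats.kruskal(*groups)
            except ValueError:
                p = 1.0
            if not p < alpha:
                continue
        stats_per_class = sorted(
            (statistics.median(g), statistics.stdev(g), len(g))
            for g in groups
        )
        diffs, powers = [], []
        for (m1, s1, n1), (m2, s2, n2) in zip(stats_per_class,
                                              stats_per_class[1:]):
            diff = m2 - m1
            pooled = math.sqrt(
                ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
            )
            if pooled == 0:
                d = math.inf if diff > 0 else 0.0
            else:
                d = diff / pooled
            diffs.append(diff)
            powers.append(max(oracle_power(n1, n2, d, alpha), min_power))
        out[j] = statistics.stdev(diffs) * statistics.geometric_mean(powers)
    return out


def oracle_permutation_pvalue(groups, n_perm: int = 2000,
                              seed: int = 0) -> float:
    """Permutation p-value for an across-class location difference,
    statistic = between-class variance of group means."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]

    def stat(values):
        idx = 0
        means = []
        for s in sizes:
            means.append(values[idx: idx + s].mean())
            idx += s
        return np.var(means)

    obs = stat(pooled)
    count = 0
    for _ in range(n_perm):
        count += stat(rng.permutation(pooled)) >= obs
    return (count + 1) / (n_perm + 1)
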