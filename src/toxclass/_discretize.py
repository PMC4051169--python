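"""Supervised discretization for the entropy-based feature rankers.

Implements Fayyad-Irani recursive entropy minimization with the MDL
stopping rule, the convention of the classic machine-learning toolkits'
chi-square / information-gain / gain-ratio attribute evaluators. When MDL
accepts no cut for a feature, the ranker falls back to 10 equal-frequency
bins so continuous features still receive a (weak) score.
"""

from __future__ import annotations

import numpy as np


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a class-count vector."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _class_counts(y_codes: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(y_codes, minlength=n_classes)


def _best_cut(x: np.ndarray, y: np.ndarray, n_classes: int):
    """Best boundary cut by class-information entropy, or None.

    ``x`` must be sorted ascending; candidate cuts lie between adjacent
    distinct values.
    """
    n = len(x)
    total = _class_counts(y, n_classes)
    ent_s = _entropy(total)

    left = np.zeros(n_classes, dtype=int)
    best = None  # (weighted_entropy, cut_index)
    for i in range(n - 1):
        left[y[i]] += 1
        if x[i] == x[i + 1]:
            continue
        right = total - left
        w_ent = (i + 1) / n * _entropy(left) + (n - i - 1) / n * _entropy(right)
        if best is None or w_ent < best[0]:
            best = (w_ent, i, left.copy(), right.copy())
    if best is None:
        return None
    w_ent, i, left, right = best
    gain = ent_s - w_ent
    # MDL acceptance criterion
    k = int((total > 0).sum())
    k1 = int((left > 0).sum())
    k2 = int((right > 0).sum())
    delta = (np.log2(3.0**k - 2.0)
             - (k * ent_s - k1 * _entropy(left) - k2 * _entropy(right)))
    threshold = (np.log2(n - 1) + delta) / n
    if gain <= threshold:
        return None
    return i, (x[i] + x[i + 1]) / 2.0


def mdl_cut_points(x: np.ndarray, y_codes: np.ndarray,
                   n_classes: int) -> list[float]:
    """All cut points accepted by recursive MDL partitioning."""
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y_codes[order]

    cuts: list[float] = []
    stack = [(0, len(xs))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2:
            continue
        res = _best_cut(xs[lo:hi], ys[lo:hi], n_classes)
        if res is None:
            continue
        i, cut = res
        cuts.append(cut)
        stack.append((lo, lo + i + 1))
        stack.append((lo + i + 1, hi))
    return sorted(cuts)


def discretize(x: np.ndarray, y_codes: np.ndarray, n_classes: int,
               fallback_bins: int = 10) -> np.ndarray:
    """Return integer bin codes for one feature.

    MDL cuts when accepted; otherwise equal-frequency bins (duplicate
    quantile edges collapsed, so a constant feature becomes a single bin).
    """
    cuts = mdl_cut_points(x, y_codes, n_classes)
    if not cuts:
        qs = np.quantile(x, np.linspace(0, 1, fallback_bins + 1)[1:-1])
        cuts = sorted(set(qs.tolist()))
        if not cuts:
            return np.zeros(len(x), dtype=int)
    return np.searchsorted(np.asarray(cuts), x, side="left").astype(int)
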