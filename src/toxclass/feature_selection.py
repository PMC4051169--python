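"""Feature ranking for multi-class expression signatures.

The centerpiece is the *gradient* selector: a gene is a good multi-class
marker when its sorted per-class medians form an *irregular* staircase —
large spread among neighbor-class log2 fold changes — and when each
neighbor-class comparison is statistically well powered. Each gene's score is

    R = stdev(fold_change_1, ..., fold_change_{n-1})
        * geomean(P_1, ..., P_{n-1})

where the fold changes are successive differences of the sorted per-class
log2 medians and P_i is the power of a two-sided two-sample t-test between
sorted neighbor classes i and i+1 at the observed standardized effect size.
Note the corollaries: a gene with equal-gap staircase medians (all fold
changes equal) scores R = 0, as does a flat gene.

Also here: SVM recursive feature elimination (one-vs-rest linear SVMs,
criterion c_i = sum of squared weights, half the active set eliminated per
round), the classic attribute evaluators (chi-square, information gain,
gain ratio, ReliefF) behind one ranking contract, PCA score features, and
the across-class univariate pre-filters (one-way ANOVA, Welch ANOVA,
Kruskal-Wallis).

All selectors are scikit-learn estimators over samples x features matrices;
the ``*_rank`` functions wrap them for :class:`~toxclass.study.ExpressionStudy`
and return provenance-carrying :class:`FeatureRanking` objects.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.feature_selection import SelectorMixin
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted, check_X_y

from ._discretize import discretize
from ._relief import relieff_scores
from .power import PowerSpec, power_of_two_sample_test
from .study import ExpressionStudy

UNIVARIATE_TESTS = ("anova", "welch_anova", "kruskal_wallis")
STANDARD_METHODS = ("chisquare", "gainratio", "inforgain", "relief")
MAX_PCA_COMPONENTS = 200


# ---------------------------------------------------------------------------
# ranking container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureRanking:
    """Ordered probe ranking with the provenance of how it was produced."""

    method: str
    params: dict
    entries: tuple[tuple[str, float], ...]  # (probe_id, score), descending

    @property
    def probe_ids(self) -> list[str]:
        return [pid for pid, _ in self.entries]

    def top(self, k: int) -> list[str]:
        """Top-k probe ids; a prefix of the full ordering."""
        return self.probe_ids[:k]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.entries, columns=["probe_id", "score"])
        df.insert(0, "rank", np.arange(1, len(df) + 1))
        df["method"] = self.method
        df["params"] = ";".join(f"{k}={v}" for k, v in sorted(self.params.items()))
        return df

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GradientScore:
    """Per-probe diagnostic detail behind a gradient R score."""

    probe_id: str
    sorted_class_medians: tuple[float, ...]
    neighbor_diffs: tuple[float, ...]
    neighbor_powers: tuple[float, ...]
    R: float


# ---------------------------------------------------------------------------
# univariate across-class tests (vectorized over probes)
# ---------------------------------------------------------------------------

def _group_rows(X: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Split samples x features X into per-class feature-major blocks."""
    return [X[y == c].T for c in np.unique(y)]


def _anova_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    groups = _group_rows(X, y)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.f_oneway(*groups, axis=1)
    return _fix_degenerate(X, p)


def _welch_anova_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Welch's heteroscedastic one-way ANOVA, vectorized over features."""
    groups = _group_rows(X, y)
    k = len(groups)
    ns = np.array([g.shape[1] for g in groups], dtype=float)
    means = np.stack([g.mean(axis=1) for g in groups])        # k x p
    varis = np.stack([g.var(axis=1, ddof=1) for g in groups])  # k x p
    with np.errstate(invalid="ignore", divide="ignore"):
        w = ns[:, None] / varis
        sw = w.sum(axis=0)
        mbar = (w * means).sum(axis=0) / sw
        a = (w * (means - mbar) ** 2).sum(axis=0) / (k - 1)
        lam = ((1 - w / sw) ** 2 / (ns[:, None] - 1)).sum(axis=0)
        b = 1 + 2.0 * (k - 2) / (k**2 - 1) * lam
        f = a / b
        df2 = (k**2 - 1) / (3.0 * lam)
        p = stats.f.sf(f, k - 1, df2)
    return _fix_degenerate(X, p)


def _kruskal_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    masks = [y == c for c in classes]
    p = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        try:
            _, pj = stats.kruskal(*[col[m] for m in masks])
        except ValueError:  # all values identical
            pj = 1.0
        p[j] = 1.0 if np.isnan(pj) else pj
    return p


def _fix_degenerate(X: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Constant probes carry no class information: p = 1 by convention."""
    p = np.asarray(p, dtype=float).copy()
    constant = np.ptp(X, axis=0) == 0
    p[constant] = 1.0
    p[np.isnan(p)] = 1.0
    return p


_TEST_FUNCS = {
    "anova": _anova_pvalues,
    "welch_anova": _welch_anova_pvalues,
    "kruskal_wallis": _kruskal_pvalues,
}


def univariate_pvalues(X: np.ndarray, y: np.ndarray, test: str) -> np.ndarray:
    """Across-class p-value per feature under the chosen test."""
    if test not in _TEST_FUNCS:
        raise ValueError(f"unknown test {test!r}; choose from {UNIVARIATE_TESTS}")
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("univariate tests require at least 2 classes")
    if test != "kruskal_wallis" and counts.min() < 2:
        small = classes[counts < 2].tolist()
        raise ValueError(
            f"{test} requires >=2 samples per class; too small: {small}"
        )
    return _TEST_FUNCS[test](np.asarray(X, dtype=float), y)


def univariate_filter(
    study: ExpressionStudy,
    labels=None,
    test: str = "kruskal_wallis",
    alpha: float = 0.05,
) -> tuple[list[str], pd.Series]:
    """Probes with across-class p-value strictly below ``alpha``.

    Returns the retained probe ids and the p-values for *all* probes.
    """
    _require_log2(study, "univariate_filter")
    y = study.labels if labels is None else np.asarray(labels)
    p = univariate_pvalues(study.X, y, test)
    pvals = pd.Series(p, index=study.probe_ids, name=f"p_{test}")
    retained = pvals.index[pvals < alpha].tolist()
    return retained, pvals


# ---------------------------------------------------------------------------
# gradient selector
# ---------------------------------------------------------------------------

class GradientSelector(SelectorMixin, BaseEstimator):
    """Rank features by staircase irregularity weighted by pairwise power.

    Parameters
    ----------
    n_features : int or None
        Number of top features :meth:`transform` keeps. None keeps every
        feature that survives the pre-filter.
    prefilter : {'kruskal_wallis', 'anova', 'welch_anova'} or None
        Across-class test used to discard uninformative features
        (p >= alpha) before scoring.
    alpha : float
        Significance level of both the pre-filter and the pairwise power
        computation.
    min_power : float
        Floor applied to each pairwise power before the geometric mean.

    Attributes
    ----------
    scores_ : ndarray
        Gradient R per feature (NaN for pre-filtered features).
    pvalues_ : ndarray
        Pre-filter p-values (all features).
    ranking_ : ndarray
        Feature indices ordered best-first (survivors only). Ties in R are
        broken by pre-filter p-value ascending, then feature name.
    """

    def __init__(self, n_features: int | None = None,
                 prefilter: str | None = "kruskal_wallis",
                 alpha: float = 0.05, min_power: float = 1e-6):
        self.n_features = n_features
        self.prefilter = prefilter
        self.alpha = alpha
        self.min_power = min_power

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 3:
            raise ValueError(
                "the gradient selector is defined for at least 3 classes"
            )
        if counts.min() < 2:
            small = classes[counts < 2].tolist()
            raise ValueError(
                f"each class needs >=2 samples for the power term; "
                f"too small: {small}"
            )
        self.n_features_in_ = X.shape[1]
        spec = PowerSpec(alpha=self.alpha, min_power=self.min_power)

        if self.prefilter is not None:
            self.pvalues_ = univariate_pvalues(X, y, self.prefilter)
            survivors = np.flatnonzero(self.pvalues_ < self.alpha)
        else:
            self.pvalues_ = np.full(X.shape[1], np.nan)
            survivors = np.arange(X.shape[1])

        med = np.stack([np.median(X[y == c], axis=0) for c in classes])
        sd = np.stack([np.std(X[y == c], axis=0, ddof=1) for c in classes])
        ns = counts.astype(float)

        order = np.argsort(med, axis=0, kind="stable")        # classes sorted
        med_s = np.take_along_axis(med, order, axis=0)
        sd_s = np.take_along_axis(sd, order, axis=0)
        ns_s = np.take_along_axis(
            np.broadcast_to(ns[:, None], med.shape), order, axis=0
        )

        diffs = np.diff(med_s, axis=0)                         # (k-1) x p
        n1, n2 = ns_s[:-1], ns_s[1:]
        pooled = np.sqrt(
            ((n1 - 1) * sd_s[:-1] ** 2 + (n2 - 1) * sd_s[1:] ** 2)
            / (n1 + n2 - 2)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(diffs == 0, 0.0, diffs / pooled)
        d = np.where((pooled == 0) & (diffs > 0), np.inf, d)
        powers = power_of_two_sample_test(n1, n2, d, alpha=spec.alpha)
        powers = np.maximum(powers, spec.min_power)

        geo = np.exp(np.mean(np.log(powers), axis=0))
        spread = np.std(diffs, axis=0, ddof=1)
        r_all = spread * geo

        self.sorted_class_medians_ = med_s
        self.neighbor_diffs_ = diffs
        self.neighbor_powers_ = powers
        self.scores_ = np.where(
            np.isin(np.arange(X.shape[1]), survivors), r_all, np.nan
        )
        self.survivors_ = survivors
        self.ranking_ = _rank_with_ties(
            survivors, r_all[survivors], self.pvalues_[survivors]
        )
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "ranking_")
        k = (len(self.ranking_) if self.n_features is None
             else min(self.n_features, len(self.ranking_)))
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_[:k]] = True
        return mask

    def score_detail(self, index: int, probe_id: str | None = None
                     ) -> GradientScore:
        """Full staircase diagnostics for one feature."""
        check_is_fitted(self, "ranking_")
        return GradientScore(
            probe_id=str(index) if probe_id is None else probe_id,
            sorted_class_medians=tuple(self.sorted_class_medians_[:, index]),
            neighbor_diffs=tuple(self.neighbor_diffs_[:, index]),
            neighbor_powers=tuple(self.neighbor_powers_[:, index]),
            R=float(np.nan_to_num(self.scores_[index], nan=0.0)),
        )


def _rank_with_ties(indices: np.ndarray, scores: np.ndarray,
                    pvalues: np.ndarray) -> np.ndarray:
    """Order best-first: score desc, then p-value asc, then index asc."""
    pv = np.where(np.isnan(pvalues), np.inf, pvalues)
    order = np.lexsort((indices, pv, -scores))
    return indices[order]


# ---------------------------------------------------------------------------
# SVM-RFE
# ---------------------------------------------------------------------------

class SVMRFESelector(SelectorMixin, BaseEstimator):
    """Recursive feature elimination with one-vs-rest linear SVMs.

    Each round trains linear SVMs on the active features, scores feature i
    by c_i = sum over class weight vectors of w_i^2, and keeps only the
    top ``floor(active * (1 - elimination_fraction))`` features (at least
    one eliminated per round) until a single feature survives. Features are
    ranked by how long they survive; ties within a round by c_i.

    Attributes
    ----------
    ranking_ : ndarray
        Feature indices, best (last survivor) first.
    active_set_sizes_ : list of int
        Active-set size at each round, ending at 1.
    scores_ : ndarray
        Elimination order per feature (higher = survived longer).
    """

    def __init__(self, n_features: int | None = None,
                 elimination_fraction: float = 0.5, C: float = 1.0,
                 max_iter: int = 5000, random_state: int = 0):
        self.n_features = n_features
        self.elimination_fraction = elimination_fraction
        self.C = C
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError("SVM-RFE requires at least 2 classes")
        if not 0.0 < self.elimination_fraction < 1.0:
            raise ValueError("elimination_fraction must lie in (0, 1)")
        self.n_features_in_ = X.shape[1]

        active = np.arange(X.shape[1])
        sizes = [len(active)]
        eliminated: list[int] = []  # first-eliminated first
        round_no = 0
        while len(active) > 1:
            round_no += 1
            svm = LinearSVC(C=self.C, max_iter=self.max_iter,
                            random_state=self.random_state)
            try:
                svm.fit(X[:, active], y)
            except Exception as exc:  # pragma: no cover - backend failure
                raise RuntimeError(
                    f"linear SVM backend failed in RFE round {round_no} "
                    f"({len(active)} active features): {exc}"
                ) from exc
            c = (np.atleast_2d(svm.coef_) ** 2).sum(axis=0)
            keep_n = int(np.floor(len(active)
                                  * (1.0 - self.elimination_fraction)))
            keep_n = min(max(keep_n, 1), len(active) - 1)
            # worst first within the round: c ascending, index tie-break
            order = np.lexsort((active, c))
            eliminated.extend(active[order[: len(active) - keep_n]].tolist())
            active = np.sort(active[order[len(active) - keep_n:]])
            sizes.append(len(active))

        elimination_order = eliminated + active.tolist()
        self.scores_ = np.empty(X.shape[1])
        self.scores_[elimination_order] = np.arange(X.shape[1])
        self.ranking_ = np.array(elimination_order[::-1], dtype=int)
        self.active_set_sizes_ = sizes
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "ranking_")
        k = (len(self.ranking_) if self.n_features is None
             else min(self.n_features, len(self.ranking_)))
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_[:k]] = True
        return mask


# ---------------------------------------------------------------------------
# classic attribute evaluators
# ---------------------------------------------------------------------------

class UnivariateRanker(SelectorMixin, BaseEstimator):
    """Chi-square / information-gain / gain-ratio / ReliefF attribute
    ranking behind one contract.

    The entropy-based criteria operate on MDL-discretized expression (10
    equal-frequency bins when MDL accepts no cut); ReliefF uses k=10
    neighbors with every instance as a reference point.
    """

    def __init__(self, method: str = "inforgain",
                 n_features: int | None = None, relief_k: int = 10):
        self.method = method
        self.n_features = n_features
        self.relief_k = relief_k

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if self.method not in STANDARD_METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; "
                f"choose from {STANDARD_METHODS}"
            )
        self.n_features_in_ = X.shape[1]
        classes, y_codes = np.unique(y, return_inverse=True)
        k = len(classes)

        if self.method == "relief":
            self.scores_ = relieff_scores(X, y_codes, k=self.relief_k)
        else:
            scores = np.empty(X.shape[1])
            for j in range(X.shape[1]):
                bins = discretize(X[:, j], y_codes, k)
                scores[j] = _contingency_score(bins, y_codes, k, self.method)
            self.scores_ = scores

        self.ranking_ = _rank_with_ties(
            np.arange(X.shape[1]), self.scores_,
            np.full(X.shape[1], np.nan),
        )
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "ranking_")
        k = (len(self.ranking_) if self.n_features is None
             else min(self.n_features, len(self.ranking_)))
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_[:k]] = True
        return mask


def _entropy_bits(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _contingency_score(bins: np.ndarray, y_codes: np.ndarray, n_classes: int,
                       method: str) -> float:
    n_bins = bins.max() + 1
    table = np.zeros((n_bins, n_classes))
    np.add.at(table, (bins, y_codes), 1.0)
    n = table.sum()
    row = table.sum(axis=1)
    col = table.sum(axis=0)

    if method == "chisquare":
        if n_bins < 2:
            return 0.0
        expected = np.outer(row, col) / n
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = (table - expected) ** 2 / expected
        return float(np.nansum(terms))

    h_class = _entropy_bits(col)
    h_cond = float(sum(
        row[b] / n * _entropy_bits(table[b]) for b in range(n_bins)
    ))
    ig = h_class - h_cond
    if method == "inforgain":
        return max(ig, 0.0)
    # gain ratio
    h_attr = _entropy_bits(row)
    return max(ig, 0.0) / h_attr if h_attr > 0 else 0.0


# ---------------------------------------------------------------------------
# PCA features
# ---------------------------------------------------------------------------

class PCAFeatures(TransformerMixin, BaseEstimator):
    """Principal-component scores as classifier features.

    Components carry a deterministic sign: the loading of largest magnitude
    is made positive. At most 200 components. With ``clamp`` (used by the
    benchmark harness) a request beyond what the data supports is reduced
    to the data limit instead of raising.
    """

    def __init__(self, n_components: int = 10, clamp: bool = False):
        self.n_components = n_components
        self.clamp = clamp

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        limit = min(X.shape[0], X.shape[1], MAX_PCA_COMPONENTS)
        n_components = self.n_components
        if not 1 <= n_components <= limit:
            if self.clamp and n_components > limit:
                logging.getLogger(__name__).warning(
                    "PCA components reduced from %d to the data limit %d",
                    n_components, limit,
                )
                n_components = limit
            else:
                raise ValueError(
                    f"n_components must lie in [1, {limit}] "
                    f"for data of shape {X.shape}"
                )
        self.pca_ = PCA(n_components=n_components, svd_solver="full")
        self.pca_.fit(X)
        comps = self.pca_.components_
        flip = np.sign(comps[np.arange(comps.shape[0]),
                             np.abs(comps).argmax(axis=1)])
        flip[flip == 0] = 1.0
        self.signs_ = flip
        self.pca_.components_ = comps * flip[:, None]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "pca_")
        return self.pca_.transform(np.asarray(X, dtype=float))

    @property
    def explained_variance_ratio_(self):
        return self.pca_.explained_variance_ratio_


# ---------------------------------------------------------------------------
# study-level wrappers
# ---------------------------------------------------------------------------

def _require_log2(study: ExpressionStudy, op: str) -> None:
    if not study.log2_transformed:
        raise ValueError(f"{op} expects log2-transformed intensities")


def _ranking_from(selector, study: ExpressionStudy, method: str,
                  params: dict) -> FeatureRanking:
    probe_ids = np.asarray(study.probe_ids)
    entries = tuple(
        (str(probe_ids[i]), float(np.nan_to_num(selector.scores_[i], nan=0.0)))
        for i in selector.ranking_
    )
    return FeatureRanking(method=method, params=params, entries=entries)


def gradient_rank(
    study: ExpressionStudy,
    labels=None,
    power_spec: PowerSpec | None = None,
    prefilter: str | None = "kruskal_wallis",
) -> FeatureRanking:
    """Gradient ranking of a log2 study (pre-filtered probes are absent)."""
    _require_log2(study, "gradient_rank")
    spec = power_spec or PowerSpec()
    y = study.labels if labels is None else np.asarray(labels)
    sel = GradientSelector(prefilter=prefilter, alpha=spec.alpha,
                           min_power=spec.min_power).fit(study.X, y)
    # tie-break on probe id needs the study's ids, not bare indices
    probe_ids = np.asarray(study.probe_ids)
    surv = sel.survivors_
    pv = np.where(np.isnan(sel.pvalues_[surv]), np.inf, sel.pvalues_[surv])
    scores = np.nan_to_num(sel.scores_[surv], nan=0.0)
    order = np.lexsort((probe_ids[surv], pv, -scores))
    entries = tuple(
        (str(probe_ids[surv[i]]), float(scores[i])) for i in order
    )
    return FeatureRanking(
        method="gradient",
        params={"alpha": spec.alpha, "min_power": spec.min_power,
                "prefilter": prefilter or "none"},
        entries=entries,
    )


def svm_rfe_rank(study: ExpressionStudy, labels=None,
                 elimination_fraction: float = 0.5) -> FeatureRanking:
    _require_log2(study, "svm_rfe_rank")
    y = study.labels if labels is None else np.asarray(labels)
    sel = SVMRFESelector(elimination_fraction=elimination_fraction)
    sel.fit(study.X, y)
    return _ranking_from(
        sel, study, "svmrfe",
        {"elimination_fraction": elimination_fraction},
    )


def standard_rank(study: ExpressionStudy, labels=None,
                  method: str = "inforgain") -> FeatureRanking:
    _require_log2(study, "standard_rank")
    y = study.labels if labels is None else np.asarray(labels)
    sel = UnivariateRanker(method=method).fit(study.X, y)
    return _ranking_from(sel, study, method, {})


def pca_components(study: ExpressionStudy,
                   n_components: int = 10) -> pd.DataFrame:
    """Sample x component score matrix from the study's log2 intensities."""
    _require_log2(study, "pca_components")
    tr = PCAFeatures(n_components=n_components).fit(study.X)
    scores = tr.transform(study.X)
    return pd.DataFrame(
        scores, index=study.sample_ids,
        columns=[f"PC{i+1}" for i in range(scores.shape[1])],
    )
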