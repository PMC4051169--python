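"""Cross-validation and cross-batch evaluation harness.

Evaluates (selector x classifier x feature size) configurations with
repeated stratified k-fold cross-validation, supports independent
train/predict across acquisition batches, and quantifies overfitting as

    rate = 100 * (train_acc - pred_acc) / (train_acc + pred_acc)

i.e. the accuracy gap as a percentage of the accuracy sum, so that a
method with perfect resubstitution but poor generalization is penalized
relative to a method whose two accuracies agree.

Classifier backends are standard scikit-learn estimators behind a
name-keyed contract; the harness, not the classifiers, is the point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .feature_selection import (
    GradientSelector,
    PCAFeatures,
    SVMRFESelector,
    UnivariateRanker,
)
from .study import ExpressionStudy

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = (
    "j48", "random_forest", "naive_bayes", "simple_logistic", "smo", "libsvm",
)
SELECTOR_NAMES = (
    "gradient", "svmrfe", "chisquare", "gainratio", "inforgain", "relief",
    "pca", "none",
)
DEFAULT_FEATURE_SIZES = (10, 25, 50, 100, 200, 300, 400, 500)


@dataclass(frozen=True)
class ClassifierBackend:
    """A named classification backend with recorded hyperparameters."""

    name: str
    hyperparameters: dict = field(default_factory=dict)

    def build(self, seed: int = 0):
        return make_classifier(self.name, seed=seed, **self.hyperparameters)


def make_classifier(name: str, seed: int = 0, **hyper):
    """Instantiate a backend by its toolkit-convention name.

    j48 -> entropy-criterion decision tree; random_forest; naive_bayes ->
    Gaussian NB; simple_logistic -> multinomial logistic regression with
    built-in L2 regularization; smo -> linear-kernel SVM (pairwise
    multi-class); libsvm -> RBF-kernel SVM.
    """
    if name == "j48":
        return DecisionTreeClassifier(criterion="entropy", random_state=seed,
                                      **hyper)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, **hyper)
    if name == "naive_bayes":
        return GaussianNB(**hyper)
    if name == "simple_logistic":
        return LogisticRegression(max_iter=2000, **hyper)
    if name == "smo":
        return SVC(kernel="linear", random_state=seed, **hyper)
    if name == "libsvm":
        return SVC(kernel="rbf", random_state=seed, **hyper)
    raise ValueError(
        f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}"
    )


def make_selector(name: str, feature_size: int | None, seed: int = 0):
    """Instantiate a feature selector/transformer by name, sized to keep
    ``feature_size`` features (PCA: components)."""
    if name == "gradient":
        return GradientSelector(n_features=feature_size)
    if name == "svmrfe":
        return SVMRFESelector(n_features=feature_size, random_state=seed)
    if name in ("chisquare", "gainratio", "inforgain", "relief"):
        return UnivariateRanker(method=name, n_features=feature_size)
    if name == "pca":
        return PCAFeatures(n_components=feature_size or 10, clamp=True)
    if name == "none":
        return None
    raise ValueError(f"unknown selector {name!r}; choose from {SELECTOR_NAMES}")


# ---------------------------------------------------------------------------
# accuracy bookkeeping
# ---------------------------------------------------------------------------

def per_class_accuracy(true_labels, predicted_labels,
                       class_scheme=None) -> pd.DataFrame:
    """Correct / total among samples truly in each class, in percent.

    Classes named by ``class_scheme`` but absent from the truth appear with
    NaN accuracy so downstream tables keep a stable class axis.
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"label vectors differ in length: "
            f"{len(true_labels)} vs {len(predicted_labels)}"
        )
    classes = list(dict.fromkeys(true_labels.tolist()))
    if class_scheme is not None:
        names = list(class_scheme.class_names)
        classes = names + [c for c in classes if c not in names]
    rows = []
    for c in classes:
        mask = true_labels == c
        n = int(mask.sum())
        correct = int((predicted_labels[mask] == c).sum())
        rows.append({
            "class_label": c,
            "n": n,
            "correct": correct,
            "accuracy": 100.0 * correct / n if n else np.nan,
        })
    return pd.DataFrame(rows).set_index("class_label")


def overfitting_rate(training_accuracy: float,
                     prediction_accuracy: float) -> float:
    """Accuracy gap as a percentage of the accuracy sum.

    Antisymmetric in its arguments and zero iff the two accuracies agree;
    negative when prediction exceeds training.
    """
    for name, v in (("training", training_accuracy),
                    ("prediction", prediction_accuracy)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} accuracy must lie in [0, 100], got {v}")
    total = training_accuracy + prediction_accuracy
    if total == 0:
        raise ValueError("overfitting rate undefined when both accuracies are 0")
    return 100.0 * (training_accuracy - prediction_accuracy) / total


@dataclass(frozen=True)
class OverfitReport:
    """Training vs independent-prediction accuracy for one configuration."""

    training_accuracy: float   # percent
    prediction_accuracy: float  # percent

    @property
    def overfitting_rate(self) -> float:
        return overfitting_rate(self.training_accuracy,
                                self.prediction_accuracy)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """One benchmark-grid cell: repeated stratified CV of one configuration."""

    selector: str
    classifier: str
    feature_size: int | None
    folds: int
    iterations: int
    selection_scope: str
    seed: int
    iteration_accuracies: list[float]          # percent, one per iteration
    per_class: pd.DataFrame                    # index class, column accuracy

    @property
    def accuracy(self) -> float:
        """Overall accuracy (%) averaged over iterations."""
        return float(np.mean(self.iteration_accuracies))


def _fit_sel_transform(selector, X_train, y_train, X_test):
    if selector is None:
        return X_train, X_test
    sel = clone(selector)
    sel.fit(X_train, y_train)
    return sel.transform(X_train), sel.transform(X_test)


def _fold_iterator(y: np.ndarray, folds: int, rng_seed: int):
    n = len(y)
    if folds >= n:  # leave-one-out
        return KFold(n_splits=n).split(np.zeros(n), y)
    _, counts = np.unique(y, return_counts=True)
    n_splits = min(folds, int(counts.min()))
    if n_splits < folds:
        logger.warning(
            "stratification degraded: %d folds requested but smallest class "
            "has %d samples; using %d folds", folds, counts.min(), n_splits,
        )
    if n_splits < 2:
        raise ValueError("cross-validation needs >=2 samples in every class")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                          random_state=rng_seed)
    return skf.split(np.zeros(n), y)


def cross_validate(
    study_or_X,
    labels=None,
    selector: str | object = "gradient",
    classifier: str | object = "libsvm",
    feature_size: int | None = 50,
    folds: int = 10,
    iterations: int = 10,
    selection_scope: str = "in_fold",
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold accuracy for one configuration.

    ``selection_scope='in_fold'`` (default) re-runs feature selection inside
    every training fold, so the reported accuracy is leakage-free.
    ``'global'`` selects once on all samples before CV — the optimistic
    protocol some published benchmarks use; it leaks test information into
    the signature and is provided for replication only.
    """
    X, y = _resolve_xy(study_or_X, labels)
    if selection_scope not in ("in_fold", "global"):
        raise ValueError("selection_scope must be 'in_fold' or 'global'")
    sel = (make_selector(selector, feature_size, seed=seed)
           if isinstance(selector, str) else selector)
    clf_name = classifier if isinstance(classifier, str) else type(classifier).__name__
    sel_name = selector if isinstance(selector, str) else type(selector).__name__

    if feature_size is not None and sel is not None \
            and not isinstance(sel, PCAFeatures) and feature_size > X.shape[1]:
        raise ValueError(
            f"feature_size {feature_size} exceeds the {X.shape[1]} "
            "available features"
        )

    if selection_scope == "global" and sel is not None:
        sel_global = clone(sel)
        sel_global.fit(X, y)
        X_eff = sel_global.transform(X)
        sel_cv = None
    else:
        X_eff = X
        sel_cv = sel

    iter_acc: list[float] = []
    confusion: list[tuple[np.ndarray, np.ndarray]] = []
    for it in range(iterations):
        it_seed = seed + it  # fixed offsets from the master seed
        correct = 0
        for train_idx, test_idx in _fold_iterator(y, folds, it_seed):
            Xtr, Xte = _fit_sel_transform(
                sel_cv, X_eff[train_idx], y[train_idx], X_eff[test_idx]
            )
            clf = (make_classifier(classifier, seed=it_seed)
                   if isinstance(classifier, str) else clone(classifier))
            clf.fit(Xtr, y[train_idx])
            pred = clf.predict(Xte)
            correct += int((pred == y[test_idx]).sum())
            confusion.append((y[test_idx], pred))
        iter_acc.append(100.0 * correct / len(y))

    all_true = np.concatenate([t for t, _ in confusion])
    all_pred = np.concatenate([p for _, p in confusion])
    return CVResult(
        selector=sel_name, classifier=clf_name, feature_size=feature_size,
        folds=folds, iterations=iterations, selection_scope=selection_scope,
        seed=seed, iteration_accuracies=iter_acc,
        per_class=per_class_accuracy(all_true, all_pred),
    )


def _resolve_xy(study_or_X, labels):
    if isinstance(study_or_X, ExpressionStudy):
        X = study_or_X.X
        y = study_or_X.labels if labels is None else np.asarray(labels)
    else:
        X = np.asarray(study_or_X, dtype=float)
        y = np.asarray(labels)
    return X, y


# ---------------------------------------------------------------------------
# independent train / predict across batches
# ---------------------------------------------------------------------------

def train_predict(
    train_study: ExpressionStudy,
    test_study: ExpressionStudy,
    selector: str | object = "gradient",
    classifier: str | object = "libsvm",
    feature_size: int | None = 50,
    seed: int = 0,
) -> tuple[OverfitReport, np.ndarray]:
    """Fit on one study, predict another; selection on training data only.

    The probe universes are intersected (with a warning when they differ);
    classes present only in the test study are necessarily mispredicted and
    are scored as errors.
    """
    shared = [p for p in train_study.probe_ids
              if p in set(test_study.probe_ids)]
    if not shared:
        raise ValueError("train and test studies share no probes")
    if len(shared) < train_study.n_probes or len(shared) < test_study.n_probes:
        logger.warning(
            "probe universes differ; using the %d shared probes", len(shared)
        )
    tr = train_study.subset_probes(shared)
    te = test_study.subset_probes(shared)

    missing = sorted(set(te.labels) - set(tr.labels))
    if missing:
        logger.warning(
            "classes present only in the test study (scored as errors): %s",
            missing,
        )

    sel = (make_selector(selector, feature_size, seed=seed)
           if isinstance(selector, str) else clone(selector))
    Xtr, Xte = _fit_sel_transform(sel, tr.X, tr.labels, te.X)
    clf = (make_classifier(classifier, seed=seed)
           if isinstance(classifier, str) else clone(classifier))
    clf.fit(Xtr, tr.labels)

    train_acc = 100.0 * float((clf.predict(Xtr) == tr.labels).mean())
    pred = clf.predict(Xte)
    pred_acc = 100.0 * float((pred == te.labels).mean())
    return OverfitReport(train_acc, pred_acc), pred


# ---------------------------------------------------------------------------
# benchmark grid
# ---------------------------------------------------------------------------

def run_grid(
    study: ExpressionStudy,
    selectors=("gradient",),
    classifiers=("libsvm",),
    feature_sizes=(50,),
    folds: int = 10,
    iterations: int = 10,
    selection_scope: str = "in_fold",
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validate every (selector, classifier, feature size) cell.

    Returns one row per cell with the overall accuracy (%) and the raw
    iteration accuracies retained for dispersion estimates.
    """
    rows = []
    for sel_name in selectors:
        for size in feature_sizes:
            for clf_name in classifiers:
                cell = cross_validate(
                    study, selector=sel_name, classifier=clf_name,
                    feature_size=size, folds=folds, iterations=iterations,
                    selection_scope=selection_scope, seed=seed,
                )
                rows.append({
                    "selector": sel_name,
                    "feature_size": size,
                    "classifier": clf_name,
                    "accuracy": round(cell.accuracy, 1),
                    "iteration_accuracies": ";".join(
                        f"{a:.4f}" for a in cell.iteration_accuracies
                    ),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# two-way clustering of marker panels
# ---------------------------------------------------------------------------

def cluster_biomarkers(study: ExpressionStudy, distance: str = "euclidean",
                       linkage: str = "average"
                       ) -> tuple[list[str], list[str]]:
    """Dendrogram leaf orders for a marker-restricted study.

    Agglomerative clustering of probes (rows) and samples (columns) with the
    given metric and linkage; input rows/columns are pre-sorted by id so the
    leaf order is deterministic under permutation of the input.
    """
    if study.n_probes < 2 or study.n_samples < 2:
        raise ValueError("clustering needs at least 2 probes and 2 samples")
    ints = study.intensities.sort_index(axis=0).sort_index(axis=1)

    def leaf_order(mat: np.ndarray, ids) -> list[str]:
        Z = hierarchy.linkage(pdist(mat, metric=distance), method=linkage)
        return [ids[i] for i in hierarchy.leaves_list(Z)]

    row_order = leaf_order(ints.to_numpy(), list(ints.index))
    col_order = leaf_order(ints.to_numpy().T, list(ints.columns))
    return row_order, col_order
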