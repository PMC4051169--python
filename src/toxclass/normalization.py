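"""Two-stage intensity normalization.

Stage one scales every chip (array) by its 50th-percentile intensity so all
chips share median 1. Stage two scales every gene either by its median across
all samples ("median" mode) or by the median over the sample's matched
vehicle-control samples ("control" mode). Both stages act on linear-scale
intensities; the log2 transform comes afterwards.

The scalers are scikit-learn transformers over samples x features matrices;
the module-level functions wrap them for :class:`~toxclass.study.ExpressionStudy`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .study import ExpressionStudy

PER_CHIP_STAGE = "per_chip"
PER_GENE_STAGES = {"median": "per_gene_median", "control": "per_gene_control"}


@dataclass
class NormalizationSpec:
    """Which per-gene mode to use and which stages have been applied."""

    per_gene_mode: str = "median"
    applied: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.per_gene_mode not in PER_GENE_STAGES:
            raise ValueError(
                f"per_gene_mode must be one of {sorted(PER_GENE_STAGES)}, "
                f"got {self.per_gene_mode!r}"
            )


class ChipMedianScaler(TransformerMixin, BaseEstimator):
    """Scale each sample (row) of a samples x features matrix by its median.

    Stateless: the scaling factor is a property of the transformed chip, so
    ``fit`` learns nothing and train/test leakage is impossible.
    """

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X)
        med = np.median(X, axis=1, keepdims=True)
        if np.any(med == 0):
            bad = np.flatnonzero(med.ravel() == 0).tolist()
            raise ValueError(f"chip(s) with zero median intensity: rows {bad}")
        return X / med


class GeneMedianScaler(TransformerMixin, BaseEstimator):
    """Scale each feature (gene) by its median across the fitted samples."""

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        self.medians_ = np.median(X, axis=0)
        if np.any(self.medians_ == 0):
            bad = np.flatnonzero(self.medians_ == 0).tolist()
            raise ValueError(f"gene(s) with zero median: columns {bad}")
        return self

    def transform(self, X):
        check_is_fitted(self, "medians_")
        X = check_array(X)
        return X / self.medians_


def _require_linear(study: ExpressionStudy, op: str) -> None:
    if study.log2_transformed:
        raise ValueError(f"{op} operates on linear-scale intensities")


def per_chip_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Divide each sample's column by that column's median over all probes."""
    _require_linear(study, "per_chip_normalize")
    scaled = ChipMedianScaler().fit_transform(study.X)  # samples x probes
    ints = pd.DataFrame(
        scaled.T, index=study.intensities.index, columns=study.intensities.columns
    )
    return study.with_intensities(ints, add_stage=PER_CHIP_STAGE)


def per_gene_median_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Divide each probe's row by the row median over all samples.

    Requires per-chip normalization to have run first.
    """
    _require_linear(study, "per_gene_median_normalize")
    if PER_CHIP_STAGE not in study.stages:
        raise ValueError("per-gene normalization requires per-chip "
                         "normalization first")
    scaled = GeneMedianScaler().fit_transform(study.X)
    ints = pd.DataFrame(
        scaled.T, index=study.intensities.index, columns=study.intensities.columns
    )
    return study.with_intensities(ints, add_stage=PER_GENE_STAGES["median"])


def per_gene_control_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Divide each sample by the median profile of its matched vehicle
    controls.

    Control samples are normalized by their own group's control median, so a
    batch-wide multiplicative offset shared by a batch's treated and control
    chips cancels exactly.
    """
    _require_linear(study, "per_gene_control_normalize")
    if PER_CHIP_STAGE not in study.stages:
        raise ValueError("per-gene normalization requires per-chip "
                         "normalization first")
    ann = study.annotations
    ints = study.intensities
    out = pd.DataFrame(index=ints.index, columns=ints.columns, dtype=float)
    is_ctrl = ann["is_control"].astype(bool)
    for group, members in ann.groupby("control_group").groups.items():
        ctrl_ids = [s for s in members if is_ctrl.loc[s]]
        if not ctrl_ids:
            treated = sorted(members)
            raise ValueError(
                f"control group {group!r} has no control samples "
                f"(treated samples: {treated})"
            )
        ctrl_median = ints[ctrl_ids].median(axis=1)
        if (ctrl_median == 0).any():
            bad = ints.index[ctrl_median == 0].tolist()
            raise ValueError(
                f"zero control median in group {group!r} for probes {bad}"
            )
        cols = list(members)
        out[cols] = ints[cols].div(ctrl_median, axis=0)
    return study.with_intensities(out, add_stage=PER_GENE_STAGES["control"])


def normalize_study(study: ExpressionStudy,
                    spec: NormalizationSpec | str = "median") -> ExpressionStudy:
    """Run both stages: per-chip scaling, then the chosen per-gene mode."""
    if isinstance(spec, str):
        spec = NormalizationSpec(per_gene_mode=spec)
    out = per_chip_normalize(study)
    if spec.per_gene_mode == "median":
        out = per_gene_median_normalize(out)
    else:
        out = per_gene_control_normalize(out)
    spec.applied = out.stages
    return out
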