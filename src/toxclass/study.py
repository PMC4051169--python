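"""Core data model for a one-color microarray study.

An :class:`ExpressionStudy` bundles the probe x sample intensity matrix,
per-probe-per-sample present/absent quality flags, and per-sample annotations
(chemical, chemical class, acquisition batch, matched vehicle-control group).
Every pipeline stage consumes and returns this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = (
    "chemical",
    "class_label",
    "batch",
    "control_group",
    "is_control",
)

#: Class label used for vehicle-control samples throughout the package.
CONTROL_CLASS = "control"


class StudyValidationError(ValueError):
    """Raised when an ExpressionStudy violates a structural invariant."""


@dataclass(frozen=True)
class SampleAnnotation:
    """Annotation for a single array sample.

    Parameters
    ----------
    sample_id : str
        Unique sample identifier.
    chemical : str
        Compound the hepatocyte culture was exposed to, or the vehicle name
        for control samples.
    class_label : str
        One of the study's chemical class names; controls carry the control
        class label.
    batch : str
        Acquisition batch / dataset identifier.
    control_group : str
        Identifier linking treated samples to their matched vehicle-control
        samples.
    is_control : bool
        True for vehicle-control samples.
    """

    sample_id: str
    chemical: str
    class_label: str
    batch: str
    control_group: str
    is_control: bool


@dataclass(frozen=True)
class ClassScheme:
    """Ordered set of chemical class names with a chemical -> class lookup."""

    class_names: tuple[str, ...]
    chemical_to_class: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.class_names)) != len(self.class_names):
            raise StudyValidationError("class names must be unique")
        unknown = {
            chem: cls
            for chem, cls in self.chemical_to_class.items()
            if cls not in self.class_names
        }
        if unknown:
            raise StudyValidationError(
                f"chemicals map to unknown classes: {sorted(unknown)}"
            )

    def class_of(self, chemical: str) -> str:
        return self.chemical_to_class[chemical]


@dataclass
class ExpressionStudy:
    """Probe x sample intensity matrix with flags and sample annotations.

    Attributes
    ----------
    intensities : pandas.DataFrame
        Probes as rows (index = probe ids), samples as columns. Linear scale
        and non-negative unless ``log2_transformed``.
    flags : pandas.DataFrame
        Boolean present/absent matrix, same shape and labels as
        ``intensities`` (True = present).
    annotations : pandas.DataFrame
        One row per sample (index = sample id) with columns
        ``chemical, class_label, batch, control_group, is_control``.
    log2_transformed : bool
        Whether intensities are on the log2 scale.
    """

    intensities: pd.DataFrame
    flags: pd.DataFrame
    annotations: pd.DataFrame
    log2_transformed: bool = False
    #: processing stages already applied, e.g. ("per_chip", "per_gene_median")
    stages: tuple[str, ...] = ()

    # -- convenience accessors -------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_probes(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def X(self) -> np.ndarray:
        """Samples x probes feature matrix (classifier orientation)."""
        return self.intensities.to_numpy().T

    @property
    def labels(self) -> np.ndarray:
        """Class label per sample, aligned to ``sample_ids``."""
        return self.annotations.loc[self.sample_ids, "class_label"].to_numpy()

    def sample_annotations(self) -> list[SampleAnnotation]:
        return [
            SampleAnnotation(sample_id=str(sid), **{
                c: (bool(row[c]) if c == "is_control" else str(row[c]))
                for c in ANNOTATION_COLUMNS
            })
            for sid, row in self.annotations.iterrows()
        ]

    def copy(self) -> "ExpressionStudy":
        return replace(
            self,
            intensities=self.intensities.copy(),
            flags=self.flags.copy(),
            annotations=self.annotations.copy(),
        )

    def with_intensities(self, intensities: pd.DataFrame,
                         log2_transformed: bool | None = None,
                         add_stage: str | None = None) -> "ExpressionStudy":
        """Return a copy carrying new intensities (flags/annotations aligned)."""
        stages = self.stages + (add_stage,) if add_stage else self.stages
        return ExpressionStudy(
            intensities=intensities,
            flags=self.flags.loc[list(intensities.index),
                                 list(intensities.columns)].copy(),
            annotations=self.annotations.loc[list(intensities.columns)].copy(),
            log2_transformed=(self.log2_transformed
                              if log2_transformed is None else log2_transformed),
            stages=stages,
        )

    def subset_probes(self, probe_ids: Iterable[str]) -> "ExpressionStudy":
        idx = list(probe_ids)
        return replace(
            self,
            intensities=self.intensities.loc[idx].copy(),
            flags=self.flags.loc[idx].copy(),
            annotations=self.annotations.copy(),
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionStudy":
        cols = list(sample_ids)
        return replace(
            self,
            intensities=self.intensities[cols].copy(),
            flags=self.flags[cols].copy(),
            annotations=self.annotations.loc[cols].copy(),
        )


def build_study(
    intensities: pd.DataFrame,
    annotations: pd.DataFrame,
    flags: pd.DataFrame | None = None,
    log2_transformed: bool = False,
    class_scheme: ClassScheme | None = None,
) -> ExpressionStudy:
    """Assemble and validate an ExpressionStudy.

    A missing ``flags`` matrix means every measurement is treated as present.
    """
    if flags is None:
        flags = pd.DataFrame(
            True, index=intensities.index, columns=intensities.columns
        )
    annotations = annotations.copy()
    if "is_control" in annotations:
        annotations["is_control"] = annotations["is_control"].astype(bool)
    study = ExpressionStudy(
        intensities=intensities,
        flags=flags,
        annotations=annotations,
        log2_transformed=log2_transformed,
    )
    validate_study(study, class_scheme=class_scheme)
    return study


def validate_study(study: ExpressionStudy,
                   class_scheme: ClassScheme | None = None) -> None:
    """Check all structural invariants; raise StudyValidationError on the
    first violation, naming the offending id."""
    ints, flags, ann = study.intensities, study.flags, study.annotations

    if ints.index.has_duplicates:
        dupes = ints.index[ints.index.duplicated()].unique().tolist()
        raise StudyValidationError(f"duplicate probe ids: {dupes}")
    if ints.columns.has_duplicates:
        dupes = ints.columns[ints.columns.duplicated()].unique().tolist()
        raise StudyValidationError(f"duplicate sample ids: {dupes}")

    if flags.shape != ints.shape or not (
        flags.index.equals(ints.index) and flags.columns.equals(ints.columns)
    ):
        raise StudyValidationError(
            "flags matrix does not match intensity matrix labels/shape"
        )

    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing_cols:
        raise StudyValidationError(f"annotation columns missing: {missing_cols}")

    matrix_samples = set(ints.columns)
    ann_samples = set(ann.index)
    if matrix_samples != ann_samples:
        only_ann = sorted(ann_samples - matrix_samples)
        only_mat = sorted(matrix_samples - ann_samples)
        if only_ann:
            raise StudyValidationError(
                f"annotated samples absent from the matrix: {only_ann}"
            )
        raise StudyValidationError(
            f"matrix samples missing annotations: {only_mat}"
        )

    if not study.log2_transformed and (ints.to_numpy() < 0).any():
        raise StudyValidationError(
            "negative intensities in a linear-scale study"
        )

    # every treated sample's control_group must contain >=1 control sample
    ctrl_groups = set(ann.loc[ann["is_control"].astype(bool), "control_group"])
    treated = ann[~ann["is_control"].astype(bool)]
    orphans = sorted(
        treated.index[~treated["control_group"].isin(ctrl_groups)].tolist()
    )
    if orphans:
        raise StudyValidationError(
            f"treated samples with no matched control samples: {orphans}"
        )

    is_ctrl = ann["is_control"].astype(bool)
    bad_ctrl = sorted(
        ann.index[is_ctrl & (ann["class_label"] != CONTROL_CLASS)].tolist()
    )
    if bad_ctrl:
        raise StudyValidationError(
            f"control samples not labelled '{CONTROL_CLASS}': {bad_ctrl}"
        )

    if class_scheme is not None:
        known = set(class_scheme.class_names)
        bad = sorted(set(ann["class_label"]) - known)
        if bad:
            raise StudyValidationError(f"unknown class labels: {bad}")
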