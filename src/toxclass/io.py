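"""Tab-separated readers and writers for expression studies.

File layout
-----------
* intensity matrix: probes as rows, header row of sample ids, first column
  named ``probe_id``;
* flags matrix (optional): same layout, values ``P`` (present) / ``A``
  (absent);
* annotations: one row per sample with columns ``sample_id, chemical,
  class_label, batch, control_group, is_control``.

All files are UTF-8, tab-separated, '.' decimal.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd

from .study import (
    ANNOTATION_COLUMNS,
    ClassScheme,
    ExpressionStudy,
    StudyValidationError,
    build_study,
)

PROBE_COLUMN = "probe_id"


def read_study(
    matrix_path: str | Path,
    annotations_path: str | Path,
    flags_path: str | Path | None = None,
    class_scheme: ClassScheme | None = None,
    log2_transformed: bool = False,
) -> ExpressionStudy:
    """Read and validate a study from its TSV trio.

    A missing flags file means all flags are treated as present.
    """
    intensities = pd.read_csv(matrix_path, sep="\t", index_col=PROBE_COLUMN)
    intensities.columns = intensities.columns.astype(str)
    intensities.index = intensities.index.astype(str)

    flags = None
    if flags_path is not None:
        raw = pd.read_csv(flags_path, sep="\t", index_col=PROBE_COLUMN)
        raw.index = raw.index.astype(str)
        raw.columns = raw.columns.astype(str)
        bad = set(raw.to_numpy().ravel()) - {"P", "A"}
        if bad:
            raise StudyValidationError(f"flag values must be P/A, got {sorted(bad)}")
        flags = raw == "P"

    ann = pd.read_csv(annotations_path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in ("sample_id",) + ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise StudyValidationError(f"annotation columns missing: {missing}")
    if ann["sample_id"].duplicated().any():
        dupes = ann.loc[ann["sample_id"].duplicated(), "sample_id"].tolist()
        raise StudyValidationError(f"duplicate sample ids in annotations: {dupes}")
    ann = ann.set_index("sample_id")
    ann["is_control"] = _parse_bool(ann["is_control"])
    for col in ("chemical", "class_label", "batch", "control_group"):
        ann[col] = ann[col].astype(str)

    return build_study(
        intensities,
        ann,
        flags=flags,
        log2_transformed=log2_transformed,
        class_scheme=class_scheme,
    )


def write_study(study: ExpressionStudy, matrix_path: str | Path,
                annotations_path: str | Path,
                flags_path: str | Path | None = None) -> None:
    """Write a study as the TSV trio read by :func:`read_study`.

    Intensities are printed with full repr precision so that a
    read-after-write round-trip is value-preserving.
    """
    ints = study.intensities.copy()
    ints.index.name = PROBE_COLUMN
    ints.to_csv(matrix_path, sep="\t", float_format="%.17g")

    ann = study.annotations.copy()
    ann.index.name = "sample_id"
    ann = ann[list(ANNOTATION_COLUMNS)]
    ann.to_csv(annotations_path, sep="\t")

    if flags_path is not None:
        flg = study.flags.map(lambda present: "P" if present else "A")
        flg.index.name = PROBE_COLUMN
        flg.to_csv(flags_path, sep="\t")


def _parse_bool(series: pd.Series) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False,
    }
    def one(v):
        if isinstance(v, (bool,)):
            return v
        s = str(v).strip().lower()
        if s not in mapping:
            raise StudyValidationError(f"unparseable is_control value: {v!r}")
        return mapping[s]
    return series.map(one)


def read_class_scheme(path: str | Path | None = None) -> ClassScheme:
    """Load a class scheme from a two-column TSV (class_label, chemical).

    Rows with an empty chemical declare a class with no example chemical.
    Without a path, the bundled scheme with the study's 14 hepatocyte
    exposure classes (13 chemical classes plus the vehicle-control class)
    is returned; it is an editable fixture, not a hard-coded constant.
    """
    if path is None:
        ref = importlib.resources.files("toxclass").joinpath(
            "data/class_scheme.tsv"
        )
        with importlib.resources.as_file(ref) as p:
            return read_class_scheme(p)
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    class_names: list[str] = []
    for name in df["class_label"]:
        if name not in class_names:
            class_names.append(name)
    chem_map = {
        str(row["chemical"]): str(row["class_label"])
        for _, row in df.iterrows()
        if str(row.get("chemical", "")) != ""
    }
    return ClassScheme(tuple(class_names), chem_map)
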