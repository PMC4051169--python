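"""End-to-end pipeline: preprocess -> normalize -> filter -> select -> benchmark.

A :class:`RunConfig` (usually loaded from YAML) names the input study (a TSV
trio on disk or a synthetic-study spec), the normalization mode, the
univariate filter, the selector/classifier/feature-size grid, the
cross-validation settings and the master seed. :func:`run_pipeline` executes
the stages, logs sample/probe counts after each one, and writes rankings, the
benchmark grid and a Table-style summary into the output directory; every
output file carries the config hash and seed, and a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import benchmark, feature_selection, normalization, preprocess, synthetic
from .io import read_study, write_study
from .study import ExpressionStudy

logger = logging.getLogger(__name__)

#: The seven benchmark configurations of the published cross-batch
#: comparison: (selector, feature size, classifier).
BENCHMARK_CONFIGS = (
    ("svmrfe", 200, "libsvm"),
    ("relief", 500, "simple_logistic"),
    ("inforgain", 500, "simple_logistic"),
    ("chisquare", 400, "simple_logistic"),
    ("gainratio", 500, "simple_logistic"),
    ("pca", 200, "smo"),
    ("gradient", 300, "smo"),
)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; YAML-serializable."""

    # input: either a TSV trio ...
    matrix_path: str | None = None
    annotations_path: str | None = None
    flags_path: str | None = None
    # ... or a synthetic spec (kwargs of SyntheticSpec)
    synthetic: dict | None = None

    normalization_mode: str = "median"
    floor: float = 5.0
    qc_min_correlation: float = 0.80
    flag_fraction: float = 0.50
    filter_test: str = "kruskal_wallis"
    filter_alpha: float = 0.05

    selectors: tuple = ("gradient",)
    feature_sizes: tuple = (300,)
    classifiers: tuple = ("smo",)
    grid: tuple | None = None   # explicit (selector, size, classifier) rows

    folds: int = 10
    iterations: int = 10
    selection_scope: str = "in_fold"
    train_batch: str | None = None  # set both to run cross-batch prediction
    test_batch: str | None = None

    seed: int = 0
    out_dir: str = "toxclass_results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.matrix_path is None and self.synthetic is None:
            raise ValueError("config must name a matrix_path or a synthetic spec")
        if self.normalization_mode not in ("median", "control"):
            raise ValueError(
                f"unknown normalization_mode {self.normalization_mode!r}"
            )
        if self.filter_test not in feature_selection.UNIVARIATE_TESTS:
            raise ValueError(f"unknown filter_test {self.filter_test!r}")
        for sel, _, clf in self.rows():
            if sel not in benchmark.SELECTOR_NAMES:
                raise ValueError(f"unknown selector {sel!r}")
            if clf not in benchmark.CLASSIFIER_NAMES:
                raise ValueError(f"unknown classifier {clf!r}")
        if (self.train_batch is None) != (self.test_batch is None):
            raise ValueError("set both train_batch and test_batch, or neither")

    def rows(self) -> list[tuple[str, int, str]]:
        """The (selector, feature size, classifier) cells to evaluate."""
        if self.grid is not None:
            return [tuple(r) for r in self.grid]
        return [
            (s, int(k), c)
            for s in self.selectors
            for k in self.feature_sizes
            for c in self.classifiers
        ]

    def digest(self) -> str:
        """Hash of the analysis-relevant settings (output paths excluded,
        so reruns into different directories stay comparable)."""
        record = dataclasses.asdict(self)
        record.pop("out_dir", None)
        blob = json.dumps(record, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_input(config: RunConfig) -> ExpressionStudy:
    if config.matrix_path is not None:
        return read_study(config.matrix_path, config.annotations_path,
                          flags_path=config.flags_path)
    spec_kwargs = dict(config.synthetic or {})
    spec_kwargs.setdefault("seed", config.seed)
    study, _ = synthetic.generate_study(synthetic.SyntheticSpec(**spec_kwargs))
    return study


def preprocess_study(study: ExpressionStudy,
                     config: RunConfig) -> ExpressionStudy:
    """Floor, QC, flag filter, normalize, log2 — counts logged per stage."""
    logger.info("input: %d probes x %d samples", study.n_probes,
                study.n_samples)
    study = preprocess.floor_intensities(study, config.floor)
    study, excluded = preprocess.qc_filter_samples(
        study, config.qc_min_correlation
    )
    logger.info("sample QC: %d samples kept, %d excluded %s",
                study.n_samples, len(excluded), excluded or "")
    study = preprocess.flag_filter_probes(study, config.flag_fraction)
    logger.info("flag filter: %d probes kept", study.n_probes)
    study = normalization.normalize_study(study, config.normalization_mode)
    study = preprocess.log2_transform(study)
    return study


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory.

    Any stage failure propagates with the stage named — no partial-result
    silence.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# config={config.digest()} seed={config.seed}\n"

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    root = logging.getLogger("toxclass")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        stage = "load_input"
        study = load_input(config)
        stage = "preprocess"
        study = preprocess_study(study, config)

        stage = "univariate_filter"
        retained, pvals = feature_selection.univariate_filter(
            study, test=config.filter_test, alpha=config.filter_alpha
        )
        logger.info("univariate filter (%s, alpha=%g): %d of %d probes",
                    config.filter_test, config.filter_alpha,
                    len(retained), study.n_probes)
        filtered = study.subset_probes(retained)

        stage = "rank"
        selectors_used = sorted({s for s, _, _ in config.rows()})
        for sel_name in selectors_used:
            if sel_name in ("pca", "none"):
                continue
            ranking = _rank_study(filtered, sel_name)
            path = out / f"ranking_{sel_name}.tsv"
            _write_with_header(ranking.to_frame(), path, header)

        stage = "benchmark"
        summary_rows = []
        cross_batch = config.train_batch is not None
        for sel_name, size, clf_name in config.rows():
            if cross_batch:
                tr = _batch_subset(filtered, config.train_batch)
                te = _batch_subset(filtered, config.test_batch)
                report, _ = benchmark.train_predict(
                    tr, te, selector=sel_name, classifier=clf_name,
                    feature_size=size, seed=config.seed,
                )
                summary_rows.append({
                    "method": sel_name,
                    "feature_number": size,
                    "classifier": clf_name,
                    "training_accuracy": round(report.training_accuracy, 1),
                    "prediction_accuracy": round(report.prediction_accuracy, 1),
                    "overfitting_rate": round(report.overfitting_rate, 2),
                })
            else:
                cell = benchmark.cross_validate(
                    filtered, selector=sel_name, classifier=clf_name,
                    feature_size=size, folds=config.folds,
                    iterations=config.iterations,
                    selection_scope=config.selection_scope, seed=config.seed,
                )
                summary_rows.append({
                    "method": sel_name,
                    "feature_number": size,
                    "classifier": clf_name,
                    "cv_accuracy": round(cell.accuracy, 1),
                })
        summary = pd.DataFrame(summary_rows)
        _write_with_header(summary, out / "summary.tsv", header)

        stage = "write_study"
        write_study(filtered, out / "study_processed.tsv",
                    out / "annotations_processed.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


def _rank_study(study: ExpressionStudy, sel_name: str):
    if sel_name == "gradient":
        return feature_selection.gradient_rank(study)
    if sel_name == "svmrfe":
        return feature_selection.svm_rfe_rank(study)
    return feature_selection.standard_rank(study, method=sel_name)


def _batch_subset(study: ExpressionStudy, batch: str) -> ExpressionStudy:
    samples = study.annotations.index[study.annotations["batch"] == batch]
    if len(samples) == 0:
        raise ValueError(f"no samples in batch {batch!r}")
    return study.subset_samples(samples)


def _write_with_header(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def export_cluster_orders(study: ExpressionStudy, marker_ids,
                          out_dir: str | Path, header: str = "") -> None:
    """Write dendrogram leaf orders for a marker panel as two TSVs."""
    rows, cols = benchmark.cluster_biomarkers(study.subset_probes(marker_ids))
    out = Path(out_dir)
    _write_with_header(pd.DataFrame({"probe_id": rows}),
                       out / "cluster_row_order.tsv", header)
    _write_with_header(pd.DataFrame({"sample_id": cols}),
                       out / "cluster_col_order.tsv", header)
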