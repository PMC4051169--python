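"""Probe- and sample-level preprocessing.

Mirrors the scanner-side conventions of one-color Agilent arrays: raw
intensities are floored at a detection limit, samples failing an
average-correlation QC are dropped, probes absent in most arrays are
discarded, and intensities are log2 transformed for statistics.
"""

from __future__ import annotations

import numpy as np

from .study import ExpressionStudy

DEFAULT_FLOOR = 5.0


def floor_intensities(study: ExpressionStudy,
                      floor: float = DEFAULT_FLOOR) -> ExpressionStudy:
    """Replace every intensity below ``floor`` by ``floor``.

    Idempotent and monotone; only defined on linear-scale data.
    """
    if study.log2_transformed:
        raise ValueError("floor_intensities requires linear-scale intensities")
    if floor <= 0:
        raise ValueError("floor must be positive")
    return study.with_intensities(study.intensities.clip(lower=floor))


def qc_filter_samples(
    study: ExpressionStudy,
    min_mean_correlation: float = 0.80,
) -> tuple[ExpressionStudy, list[str]]:
    """Drop samples poorly correlated with the rest of the experiment.

    For each sample the mean Pearson correlation with every other sample is
    computed on log2 intensities (linear input is floored at the detection
    limit and logged internally); a sample is excluded iff its mean
    correlation is strictly below ``min_mean_correlation``.

    Returns the surviving study and the list of excluded sample ids.
    """
    if study.n_samples < 3:
        raise ValueError("sample QC requires at least 3 samples")
    if study.log2_transformed:
        values = study.intensities
    else:
        values = np.log2(study.intensities.clip(lower=DEFAULT_FLOOR))
    corr = values.corr(method="pearson")  # samples x samples
    n = corr.shape[0]
    # mean over the other samples (exclude self-correlation 1.0)
    mean_corr = (corr.sum(axis=0) - 1.0) / (n - 1)
    excluded = mean_corr.index[mean_corr < min_mean_correlation].tolist()
    kept = [s for s in study.sample_ids if s not in set(excluded)]
    return study.subset_samples(kept), list(excluded)


def flag_filter_probes(study: ExpressionStudy,
                       min_present_fraction: float = 0.50) -> ExpressionStudy:
    """Keep a probe iff its fraction of present flags >= the threshold."""
    frac = study.flags.mean(axis=1)
    keep = study.flags.index[frac >= min_present_fraction]
    return study.subset_probes(keep)


def log2_transform(study: ExpressionStudy) -> ExpressionStudy:
    """Elementwise log2; errors on a second transform or non-positive data."""
    if study.log2_transformed:
        raise ValueError("study is already log2 transformed")
    if (study.intensities.to_numpy() <= 0).any():
        raise ValueError("log2 transform requires strictly positive intensities")
    return study.with_intensities(np.log2(study.intensities),
                                  log2_transformed=True)
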