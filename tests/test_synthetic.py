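"""The synthetic study generator: determinism, ground truth, structure."""

import numpy as np
import pytest

from toxclass import (
    MarkerBlock,
    SyntheticSpec,
    cluster_biomarkers,
    generate_study,
    gradient_rank,
    log2_transform,
    normalize_study,
    floor_intensities,
    validate_study,
)


def _small_spec(**kw):
    base = dict(n_classes=5, n_chemicals=8, replicates=3, n_probes=120,
                n_planted_markers=10, n_batches=1, seed=3)
    base.update(kw)
    return SyntheticSpec(**base)


def test_same_seed_bit_identical():
    a, _ = generate_study(_small_spec())
    b, _ = generate_study(_small_spec())
    assert a.intensities.equals(b.intensities)
    assert a.flags.equals(b.flags)
    assert a.annotations.equals(b.annotations)


def test_different_seed_differs():
    a, _ = generate_study(_small_spec(seed=1))
    b, _ = generate_study(_small_spec(seed=2))
    assert not a.intensities.equals(b.intensities)


def test_generated_study_validates():
    study, _ = generate_study(_small_spec(n_batches=2))
    validate_study(study)
    ann = study.annotations
    assert set(ann["batch"]) == {"D1", "D2"}
    assert ann["is_control"].any()
    # >= `replicates` biological replicates per chemical
    treated = ann[~ann["is_control"]]
    assert treated.groupby(["chemical", "batch"]).size().min() >= 3


def test_zero_noise_zero_effect_samples_identical_up_to_batch():
    spec = _small_spec(n_planted_markers=0, noise_sigma=0.0,
                       chip_scale_sigma=0.0, n_batches=2, batch_offset=1.5,
                       absent_flag_rate=0.0)
    study, _ = generate_study(spec)
    ann = study.annotations
    d1 = study.intensities[ann.index[ann["batch"] == "D1"]]
    d2 = study.intensities[ann.index[ann["batch"] == "D2"]]
    # within a batch all samples identical
    assert (d1.nunique(axis=1) == 1).all()
    assert (d2.nunique(axis=1) == 1).all()
    # across batches: the multiplicative offset (where not floored)
    unfloored = (d1.iloc[:, 0] > 5.0) & (d2.iloc[:, 0] > 5.0)
    ratio = (d2.iloc[:, 0] / d1.iloc[:, 0])[unfloored]
    np.testing.assert_allclose(ratio, 1.5, rtol=1e-12)


def test_ground_truth_effects_recovered_from_noiseless_data():
    spec = _small_spec(noise_sigma=0.0, chip_scale_sigma=0.0, n_batches=1,
                       baseline_log2_mean=10.0, baseline_log2_sigma=0.0,
                       absent_flag_rate=0.0)
    study, truth = generate_study(spec)
    logged = np.log2(study.intensities)
    ann = study.annotations
    for pid in truth.marker_ids:
        for cls in spec.class_names:
            samples = ann.index[ann["class_label"] == cls]
            est = float(logged.loc[pid, samples].median()) \
                - float(truth.baseline_log2[pid])
            assert est == pytest.approx(truth.effects.loc[pid, cls],
                                        abs=1e-9)


def test_flag_rate_and_marker_flags():
    spec = _small_spec(absent_flag_rate=0.3, n_probes=300)
    study, truth = generate_study(spec)
    assert study.flags.loc[list(truth.marker_ids)].all().all()
    observed_absent = 1.0 - study.flags.mean().mean()
    assert observed_absent == pytest.approx(0.3 * (1 - 10 / 300), abs=0.03)


def test_infeasible_specs_rejected():
    with pytest.raises(ValueError, match="markers"):
        _small_spec(n_planted_markers=500)
    with pytest.raises(ValueError, match="3 classes"):
        _small_spec(n_classes=2)
    with pytest.raises(ValueError, match="unknown classes"):
        _small_spec(marker_blocks=(
            MarkerBlock(2, ("nonexistent",), ("metals",)),
        ))


def test_noise_degrades_marker_recovery_monotonically():
    """Average top-k recovery over seeds never improves as sigma grows."""
    sigmas = (0.1, 0.8, 2.5)
    mean_hits = []
    for sigma in sigmas:
        hits = []
        for seed in range(3):
            spec = _small_spec(n_probes=200, n_planted_markers=15,
                               noise_sigma=sigma, seed=seed,
                               marker_effect=2.0)
            study, truth = generate_study(spec)
            s = log2_transform(normalize_study(floor_intensities(study),
                                               "median"))
            ranking = gradient_rank(s)
            hits.append(len(set(ranking.top(30)) & set(truth.marker_ids)))
        mean_hits.append(np.mean(hits))
    assert mean_hits[0] >= mean_hits[1] >= mean_hits[2]


class TestScreeningFixture:
    def test_validates_and_has_expected_shape(self, screening_study):
        study, truth = screening_study
        validate_study(study)
        assert len(set(study.annotations["class_label"])) == 14
        assert set(study.annotations["batch"]) == {"D1", "D2"}
        assert len(truth.block_marker_ids) == 30

    def test_batches_separable_before_not_after_normalization(
            self, screening_study):
        """Batch classification is evaluated with vehicle-control groups
        held out together, so only genuine batch signal (not memorized
        group signatures) can drive the accuracy."""
        from sklearn.model_selection import GroupKFold
        from sklearn.svm import SVC

        study, _ = screening_study
        batches = study.annotations["batch"].to_numpy()
        groups = study.annotations["control_group"].to_numpy()

        def batch_cv_accuracy(X):
            correct = 0
            for tr, te in GroupKFold(n_splits=3).split(X, batches, groups):
                clf = SVC(kernel="linear").fit(X[tr], batches[tr])
                correct += (clf.predict(X[te]) == batches[te]).sum()
            return 100.0 * correct / len(batches)

        raw = log2_transform(study.copy())
        assert batch_cv_accuracy(raw.X) > 90.0
        normed = log2_transform(
            normalize_study(floor_intensities(study), "control")
        )
        assert abs(batch_cv_accuracy(normed.X) - 50.0) <= 10.0

    def test_block_marker_classes_cluster_contiguously(self, screening_study):
        study, truth = screening_study
        normed = log2_transform(
            normalize_study(floor_intensities(study), "median")
        )
        block = normed.subset_probes(truth.block_marker_ids)
        # cluster class-median profiles, as in a class-level heatmap
        med = block.intensities.T.groupby(
            normed.annotations["class_label"]
        ).median().T
        from toxclass import build_study
        import pandas as pd

        ann = pd.DataFrame(
            {"chemical": "none", "class_label": "control", "batch": "D1",
             "control_group": "g", "is_control": True},
            index=pd.Index(med.columns, name="sample_id"),
        )
        class_study = build_study(med, ann, log2_transformed=True)
        _, col_order = cluster_biomarkers(class_study)
        down = {"metals", "inflammatory mediators"}
        pos = sorted(col_order.index(c) for c in down)
        assert pos[1] - pos[0] == 1  # the two down classes are adjacent
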