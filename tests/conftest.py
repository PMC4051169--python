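import numpy as np
import pandas as pd
import pytest

from toxclass import build_study
from toxclass.study import CONTROL_CLASS


def make_tiny_study(values, class_labels, batches=None, log2=False,
                    control_groups=None, probe_prefix="p"):
    """Build a small validated study from a probes x samples array.

    One control sample per control group is appended automatically unless
    the label list already contains controls.
    """
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    probe_ids = [f"{probe_prefix}{i}" for i in range(n_probes)]
    sample_ids = [f"s{i}" for i in range(n_samples)]
    batches = batches or ["D1"] * n_samples
    control_groups = control_groups or ["g0"] * n_samples
    rows = []
    for sid, lab, b, g in zip(sample_ids, class_labels, batches,
                              control_groups):
        rows.append((sid, f"chem_{lab}", lab, b, g, lab == CONTROL_CLASS))
    has_control = any(lab == CONTROL_CLASS for lab in class_labels)
    ints = pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    if not has_control:
        # two vehicle controls per referenced group so validation and
        # per-class sample-size checks pass
        for g in dict.fromkeys(control_groups):
            for tag, factor in (("a", 1.0), ("b", 1.01)):
                cid = f"ctrl_{g}_{tag}"
                ints[cid] = values.mean(axis=1) * factor
                rows.append((cid, "vehicle", CONTROL_CLASS, batches[0], g,
                             True))
    ann = pd.DataFrame(
        rows, columns=["sample_id", "chemical", "class_label", "batch",
                       "control_group", "is_control"],
    ).set_index("sample_id")
    return build_study(ints, ann, log2_transformed=log2)


@pytest.fixture(scope="session")
def screening_study():
    """Small-scale analogue of the two-batch 14-class screening design."""
    from toxclass import make_screening_fixture

    return make_screening_fixture(seed=7, n_probes=600)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
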