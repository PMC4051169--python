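"""Synthetic hepatocyte-exposure studies with planted structure.

The generator emulates the statistical shape the pipeline assumes in a
one-color microarray chemical-screening design: a control class plus
treated chemical classes, >=3 replicates per chemical, matched vehicle
controls per small chemical group, two acquisition batches carrying a
multiplicative chip offset, a scanner intensity floor, log-normal
measurement noise, planted marker genes whose per-class medians form a
staircase on the log2 scale (irregular-gap staircases are the gradient
selector's intended catch; equal-gap staircases score zero by design),
optional marker *blocks* co-regulated across a set of classes, and null
genes. Ground truth is returned for recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .study import CONTROL_CLASS, ExpressionStudy, build_study

DEFAULT_CLASSES = (
    "anti-microbial",
    "cancer-related drugs",
    "energetics",
    "halogenated contaminants",
    "hormones and endocrine disruptors",
    "inflammatory mediators",
    "lipid and peroxisomal mediators",
    "metals",
    "oxidative stress mediators",
    "pesticides",
    "polyaromatic hydrocarbons",
    "PPCPs",
    "PXR mediators",
)


@dataclass(frozen=True)
class MarkerBlock:
    """A set of markers sharing direction across class groups."""

    n_markers: int
    down_classes: tuple[str, ...]
    up_classes: tuple[str, ...]
    amplitude: float = 2.0  # log2 units


@dataclass
class SyntheticSpec:
    """Study-design parameters for :func:`generate_study`.

    Defaults mirror the screening design the pipeline targets: 14 classes
    (13 chemical classes plus control), 105 chemicals, 3 biological
    replicates per chemical per batch, matched vehicle controls for every
    group of 3 chemicals, and two acquisition batches.
    """

    n_classes: int = 14                      # including the control class
    n_chemicals: int = 105                   # across non-control classes
    replicates: int = 3                      # per chemical per batch
    n_probes: int = 2000
    n_planted_markers: int = 50
    marker_gap: str = "irregular"            # or "uniform"
    marker_effect: float = 3.0               # total staircase range, log2
    marker_blocks: tuple[MarkerBlock, ...] = ()
    n_batches: int = 2
    batch_offset: float = 1.5                # multiplicative chip factor
    chip_scale_sigma: float = 0.1            # per-chip log2-normal scale
    noise_sigma: float = 0.2                 # per-measurement log2-normal
    baseline_log2_mean: float = 8.0
    baseline_log2_sigma: float = 2.0
    floor: float = 5.0
    chemicals_per_control: int = 3           # chemicals per vehicle group
    absent_flag_rate: float = 0.05
    class_names: tuple[str, ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 3:
            raise ValueError("need at least 3 classes")
        if self.marker_gap not in ("irregular", "uniform"):
            raise ValueError("marker_gap must be 'irregular' or 'uniform'")
        if not 0.0 <= self.absent_flag_rate <= 1.0:
            raise ValueError("absent_flag_rate must lie in [0, 1]")
        if not self.class_names:
            n_treated = self.n_classes - 1
            if n_treated <= len(DEFAULT_CLASSES):
                names = DEFAULT_CLASSES[:n_treated]
            else:
                names = DEFAULT_CLASSES + tuple(
                    f"class_{i}" for i in range(len(DEFAULT_CLASSES), n_treated)
                )
            self.class_names = (CONTROL_CLASS,) + names
        if len(self.class_names) != self.n_classes:
            raise ValueError("class_names length must equal n_classes")
        for block in self.marker_blocks:
            unknown = (set(block.down_classes) | set(block.up_classes)) \
                - set(self.class_names)
            if unknown:
                raise ValueError(
                    f"marker block names unknown classes: {sorted(unknown)}"
                )
        total_markers = self.n_planted_markers + sum(
            b.n_markers for b in self.marker_blocks
        )
        if total_markers > self.n_probes:
            raise ValueError("more planted markers than probes")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: marker ids and the per-class log2 effect table."""

    marker_ids: tuple[str, ...]          # irregular/uniform staircase markers
    block_marker_ids: tuple[str, ...]
    effects: pd.DataFrame                # probes x classes, log2 offsets
    baseline_log2: pd.Series             # per-probe baseline


def generate_study(spec: SyntheticSpec) -> tuple[ExpressionStudy, GroundTruth]:
    """Generate a fully annotated study plus its ground truth.

    Linear intensities are baseline x 2^(class effect) x batch factor x
    chip factor x 2^(noise), floored at ``spec.floor`` to emulate the
    scanner detection limit. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    classes = list(spec.class_names)
    treated_classes = [c for c in classes if c != CONTROL_CLASS]

    # ---- probes and planted effects -----------------------------------
    probe_ids = [f"probe_{i:05d}" for i in range(spec.n_probes)]
    effects = pd.DataFrame(0.0, index=probe_ids, columns=classes)

    marker_idx = rng.choice(spec.n_probes,
                            size=spec.n_planted_markers
                            + sum(b.n_markers for b in spec.marker_blocks),
                            replace=False)
    stair_idx = marker_idx[: spec.n_planted_markers]
    marker_ids = tuple(probe_ids[i] for i in stair_idx)

    k = len(classes)
    for i in stair_idx:
        if spec.marker_gap == "uniform":
            gaps = np.full(k - 1, spec.marker_effect / (k - 1))
        else:
            gaps = rng.dirichlet(np.ones(k - 1)) * spec.marker_effect
        heights = np.concatenate([[0.0], np.cumsum(gaps)])
        effects.iloc[i] = heights[rng.permutation(k)]

    block_ids: list[str] = []
    offset = spec.n_planted_markers
    for block in spec.marker_blocks:
        idx = marker_idx[offset: offset + block.n_markers]
        offset += block.n_markers
        for i in idx:
            pid = probe_ids[i]
            block_ids.append(pid)
            for c in block.down_classes:
                effects.loc[pid, c] = -block.amplitude
            for c in block.up_classes:
                effects.loc[pid, c] = block.amplitude

    baseline_log2 = pd.Series(
        rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sigma,
                   spec.n_probes),
        index=probe_ids,
    )

    # ---- sample layout -------------------------------------------------
    chem_class = {}
    for j in range(spec.n_chemicals):
        chem_class[f"chem_{j:03d}"] = treated_classes[j % len(treated_classes)]
    chemicals = sorted(chem_class)

    records = []  # sample_id, chemical, class, batch, control_group, is_ctrl
    batches = [f"D{b+1}" for b in range(spec.n_batches)]
    for batch in batches:
        seen_groups = set()
        for j, chem in enumerate(chemicals):
            group = f"vg{j // spec.chemicals_per_control:03d}_{batch}"
            if group not in seen_groups:
                seen_groups.add(group)
                for r in range(spec.replicates):
                    records.append((
                        f"{batch}_{group}_ctrl_r{r+1}", "vehicle",
                        CONTROL_CLASS, batch, group, True,
                    ))
            for r in range(spec.replicates):
                records.append((
                    f"{batch}_{chem}_r{r+1}", chem, chem_class[chem],
                    batch, group, False,
                ))
    ann = pd.DataFrame(
        records,
        columns=["sample_id", "chemical", "class_label", "batch",
                 "control_group", "is_control"],
    ).set_index("sample_id")

    # ---- intensities ----------------------------------------------------
    n_samples = len(ann)
    class_codes = ann["class_label"].map(
        {c: i for i, c in enumerate(classes)}
    ).to_numpy()
    batch_codes = ann["batch"].map(
        {b: i for i, b in enumerate(batches)}
    ).to_numpy()

    eff = effects.to_numpy()[:, class_codes]             # probes x samples
    log2_signal = baseline_log2.to_numpy()[:, None] + eff
    chip_scale = rng.normal(0.0, spec.chip_scale_sigma, n_samples)
    batch_log2 = np.log2(spec.batch_offset) * batch_codes
    noise = rng.normal(0.0, spec.noise_sigma, (spec.n_probes, n_samples))
    linear = 2.0 ** (log2_signal + chip_scale[None, :]
                     + batch_log2[None, :] + noise)
    linear = np.maximum(linear, spec.floor)

    intensities = pd.DataFrame(linear, index=probe_ids, columns=ann.index)

    flags = pd.DataFrame(
        rng.random((spec.n_probes, n_samples)) >= spec.absent_flag_rate,
        index=probe_ids, columns=ann.index,
    )
    flags.loc[list(marker_ids) + block_ids] = True  # markers always detected

    study = build_study(intensities, ann, flags=flags)
    truth = GroundTruth(
        marker_ids=marker_ids,
        block_marker_ids=tuple(block_ids),
        effects=effects,
        baseline_log2=baseline_log2,
    )
    return study, truth


def make_screening_fixture(seed: int = 0,
                              n_probes: int = 2000
                              ) -> tuple[ExpressionStudy, GroundTruth]:
    """Small-scale analogue of the full screening design.

    14 classes x 2 chemicals per treated class x 3 replicates x 2 batches,
    with 50 irregular-staircase markers plus a 30-marker block that is
    down-regulated in the metal and inflammatory classes and up-regulated
    in four others — the co-regulation pattern integration tests and docs
    exercise.
    """
    block = MarkerBlock(
        n_markers=30,
        down_classes=("metals", "inflammatory mediators"),
        up_classes=("anti-microbial", "cancer-related drugs",
                    "pesticides", "PXR mediators"),
        amplitude=2.0,
    )
    spec = SyntheticSpec(
        n_classes=14,
        n_chemicals=26,
        replicates=3,
        n_probes=n_probes,
        n_planted_markers=50,
        marker_blocks=(block,),
        seed=seed,
    )
    return generate_study(spec)
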