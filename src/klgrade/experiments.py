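"""Desk-scale reference experiment: the three evaluation scenarios.

Reproduces, on synthetic cohorts, the experimental design of the grading
study: (1) internal evaluation under a patient-wise stratified split;
(2) zero-shot transfer of the internally trained model to an external,
domain-shifted cohort; (3) selective fine-tuning on the external train/val
partitions followed by held-out external test evaluation, with cutpoints
retuned on the external validation split.

Study conditions (fixed once): an internal bilateral cohort of 300
patients (600 images) and an external single-image cohort of 160 patients
rendered at 64x64 with a joint gap of 18 px at grade 0 shrinking 3 px per
grade and intensity noise sd 6; the external cohort carries the fixed
brightness/contrast/letterbox domain shift.  The tiny conv encoders train
for 10 epochs at base rate 2e-3 (2 warmup epochs) — a randomly initialized
small network needs a larger step size than a pretrained large one — and
fine-tune for 8 epochs at the same backbone:head rate ratio (1:5) as the
full-scale protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decode import Cutpoints, tune_cutpoints
from .inference import collect_cumulative_probs, predict_cohort
from .manifest import CohortManifest, SplitAssignment, patient_wise_split
from .metrics import qwk
from .model import ModelConfig, build_model
from .synthetic import SyntheticSpec, generate_roster, render_cohort
from .train import ImageStore, TrainConfig, finetune, fit

INTERNAL_PATIENTS = 300
EXTERNAL_PATIENTS = 160
IMAGE_SIZE = 64
PATCH_SIZE = 32
GAP_BASE = 18.0
GAP_STEP = 3.0
NOISE_SD = 6.0


def internal_spec(seed: int) -> SyntheticSpec:
    return SyntheticSpec(
        n_patients=INTERNAL_PATIENTS, bilateral=True, image_size=IMAGE_SIZE,
        gap_base=GAP_BASE, gap_step=GAP_STEP, noise_sd=NOISE_SD, seed=seed,
    )


def external_spec(seed: int) -> SyntheticSpec:
    return SyntheticSpec(
        n_patients=EXTERNAL_PATIENTS, bilateral=False, image_size=IMAGE_SIZE,
        gap_base=GAP_BASE, gap_step=GAP_STEP, noise_sd=NOISE_SD,
        domain_shift="external", seed=seed,
    )


def tiny_model_config(seed: int) -> ModelConfig:
    return ModelConfig(image_size=IMAGE_SIZE, patch_size=PATCH_SIZE,
                       feature_dim=32, seed=seed)


def tiny_train_config(seed: int) -> TrainConfig:
    return TrainConfig(base_lr=2e-3, warmup_epochs=2, max_epochs=10,
                       patience=10, batch_size=32, seed=seed)


def tiny_finetune_config(seed: int) -> TrainConfig:
    return TrainConfig(base_lr=2e-3, seed=seed, finetune=True,
                       finetune_backbone_lr=5e-4, finetune_head_lr=2.5e-3,
                       finetune_max_epochs=8, finetune_patience=8)


def materialize(spec: SyntheticSpec) -> tuple[CohortManifest, ImageStore]:
    """Roster + in-memory rendered images (no disk round-trip)."""
    manifest = generate_roster(spec)
    arrays = {rec.image: px for rec, px in render_cohort(manifest, spec)}
    return manifest, ImageStore(arrays=arrays)


@dataclass
class StudyResult:
    internal_qwk: float
    zero_shot_qwk: float
    finetuned_qwk: float
    elapsed_s: float
    train_state: object
    finetune_state: object
    internal_cutpoints: Cutpoints
    external_cutpoints: Cutpoints
    tables: dict  # predictions per scenario
    splits: dict[str, SplitAssignment]
    manifests: dict[str, CohortManifest]
    stores: dict[str, ImageStore]
    model: object


def run_domain_shift_study(seed: int = 42, tta: int = 8) -> StudyResult:
    """Train internally, transfer zero-shot, fine-tune; report the three QWKs.

    Deterministic under ``seed``; all sub-seeds derive from it.
    """
    import time

    t_start = time.perf_counter()
    seed = int(seed) % (2**31 - 3)
    iman, istore = materialize(internal_spec(seed + 1))
    eman, estore = materialize(external_spec(seed + 2))
    isplit = patient_wise_split(iman, seed=seed)
    esplit = patient_wise_split(eman, seed=seed)

    model = build_model(tiny_model_config(seed))
    state = fit(model, isplit.subset(iman, "train"), isplit.subset(iman, "val"),
                istore, tiny_train_config(seed))

    cum, grades = collect_cumulative_probs(
        model, isplit.subset(iman, "val"), istore, tta=tta)
    icuts, _ = tune_cutpoints(cum, grades, partition="val")

    t_int = predict_cohort(model, isplit.subset(iman, "test"), istore, icuts, tta=tta)
    t_zero = predict_cohort(model, esplit.subset(eman, "test"), estore, icuts, tta=tta)

    ft_state = finetune(model, esplit.subset(eman, "train"),
                        esplit.subset(eman, "val"), estore,
                        tiny_finetune_config(seed))
    cum2, grades2 = collect_cumulative_probs(
        model, esplit.subset(eman, "val"), estore, tta=tta)
    ecuts, _ = tune_cutpoints(cum2, grades2, partition="val")
    t_fine = predict_cohort(model, esplit.subset(eman, "test"), estore, ecuts, tta=tta)

    return StudyResult(
        internal_qwk=qwk(t_int["true_grade"], t_int["pred_grade"]),
        zero_shot_qwk=qwk(t_zero["true_grade"], t_zero["pred_grade"]),
        finetuned_qwk=qwk(t_fine["true_grade"], t_fine["pred_grade"]),
        elapsed_s=time.perf_counter() - t_start,
        train_state=state,
        finetune_state=ft_state,
        internal_cutpoints=icuts,
        external_cutpoints=ecuts,
        tables={"internal": t_int, "zero_shot": t_zero, "finetuned": t_fine},
        splits={"internal": isplit, "external": esplit},
        manifests={"internal": iman, "external": eman},
        stores={"internal": istore, "external": estore},
        model=model,
    )
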