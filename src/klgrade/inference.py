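"""Batch inference: TTA forward passes -> per-image prediction table."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .decode import Cutpoints, tta_aggregate
from .manifest import CohortManifest
from .model import FusionModel, HeadOutputs
from .preprocess import tta_views
from .train import ImageStore


def predict_cohort(
    model: FusionModel,
    manifest: CohortManifest,
    images: ImageStore,
    cutpoints: Cutpoints = Cutpoints(),
    tta: int = 8,
    average: str = "probability",
) -> pd.DataFrame:
    """Predict every manifest record; returns the standard predictions table.

    Columns: image, patient_id, true_grade, pred_grade, p0..p4 (class
    probabilities from the distribution head), cum1..cum4 (cumulative
    ordinal probabilities), p_ge2, binary_prob.  Multitask models only;
    the flat/merged baselines are scored from their own argmax instead.
    """
    if model.config.head_set != "multitask":
        raise ValueError("TTA ordinal decoding requires the multitask head set")
    size = model.config.image_size
    patch = model.config.patch_size
    rows = []
    for rec in manifest.frame.itertuples(index=False):
        views = tta_views(images.get(rec.image), size, patch, tta=tta)
        outs, _ = model.forward(views, train=False)
        per_view = [
            HeadOutputs(
                ordinal_logits=outs.ordinal_logits[i : i + 1],
                ld_logits=outs.ld_logits[i : i + 1],
                binary_logit=outs.binary_logit[i : i + 1],
            )
            for i in range(len(views))
        ]
        pred = tta_aggregate(per_view, cutpoints, average=average)
        row = {
            "image": rec.image,
            "patient_id": rec.patient_id,
            "true_grade": int(rec.kl_grade),
            "pred_grade": pred.grade,
            "p_ge2": pred.p_ge2,
            "binary_prob": pred.binary_head_prob,
        }
        row.update({f"p{c}": pred.class_probs[c] for c in range(5)})
        row.update({f"cum{k+1}": pred.cumulative_probs[k] for k in range(4)})
        rows.append(row)
    return pd.DataFrame(rows)


def collect_cumulative_probs(
    model: FusionModel,
    manifest: CohortManifest,
    images: ImageStore,
    tta: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """(N, 4) TTA-averaged cumulative probabilities + true grades.

    The input the cutpoint tuner consumes (run it on validation only).
    """
    table = predict_cohort(model, manifest, images, Cutpoints(), tta=tta)
    cum = table[[f"cum{k}" for k in range(1, 5)]].to_numpy()
    return cum, table["true_grade"].to_numpy(dtype=int)
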