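"""Optimization loop: two-group AdamW, cosine warmup schedule, weight EMA,
early stopping on validation QWK, checkpointing, and selective fine-tuning.

Backbone parameters (encoders, including each stream's GeM exponent) and
head parameters form two optimizer groups; heads train at a multiple of the
backbone rate.  The schedule warms up linearly for ``warmup_epochs`` and
then decays with a cosine to zero at ``max_epochs``.  An exponential moving
average of all weights is maintained as a smoothed checkpoint; on each
validation-QWK improvement both raw and EMA weights are snapshotted, and at
the end whichever of the two scores the higher validation QWK becomes the
selected checkpoint.

Fine-tuning warm-starts from a checkpoint with every parameter unfrozen,
lower differentiated learning rates, a shorter patience and epoch budget,
and the same composite loss; decoding cutpoints are *not* carried over —
they are retuned on the target domain's validation split downstream.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .manifest import CohortManifest
from .model import FusionModel, ModelConfig, build_model
from .objectives import LossWeights, composite_loss
from .preprocess import AugmentPolicy, apply_augment, eval_bundle
from .metrics import qwk
from .decode import Cutpoints, decode
from .synthetic import load_image


@dataclass(frozen=True)
class TrainConfig:
    base_lr: float = 1e-4
    head_lr_multiplier: float = 2.0
    weight_decay: float = 1e-4
    warmup_epochs: int = 3
    max_epochs: int = 60
    batch_size: int = 32
    patience: int = 12
    ema_decay: float = 0.999
    seed: int = 42
    sigma: float = 1.0
    loss_weights: LossWeights = field(default_factory=LossWeights)
    augment: bool = True
    finetune: bool = False
    # fine-tuning overrides (applied when finetune=True)
    finetune_backbone_lr: float = 1e-5
    finetune_head_lr: float = 5e-5
    finetune_patience: int = 5
    finetune_max_epochs: int = 15

    def __post_init__(self) -> None:
        if min(self.base_lr, self.head_lr_multiplier, self.ema_decay + 1) <= 0:
            raise ValueError("rates must be positive")
        if self.patience > self.max_epochs and not self.finetune:
            raise ValueError("patience must not exceed max_epochs")

    def resolved(self) -> "TrainConfig":
        """Apply the fine-tuning overrides if the flag is set."""
        if not self.finetune:
            return self
        return replace(
            self,
            base_lr=self.finetune_backbone_lr,
            head_lr_multiplier=self.finetune_head_lr / self.finetune_backbone_lr,
            patience=self.finetune_patience,
            max_epochs=self.finetune_max_epochs,
        )


def lr_at(epoch: int, config: TrainConfig) -> tuple[float, float]:
    """(backbone_lr, head_lr) at an epoch: linear warmup then cosine decay.

    Warmup ramps 0 -> base over ``warmup_epochs`` (epoch 0 takes the first
    nonzero step); from there the rate follows
    ``base * (1 + cos(pi * progress)) / 2`` reaching 0 at ``max_epochs``.
    """
    cfg = config.resolved()
    if not 0 <= epoch < cfg.max_epochs:
        raise ValueError(f"epoch must lie in [0, {cfg.max_epochs})")
    if cfg.warmup_epochs > 0 and epoch < cfg.warmup_epochs:
        base = cfg.base_lr * (epoch + 1) / cfg.warmup_epochs
    else:
        span = max(1, cfg.max_epochs - cfg.warmup_epochs)
        progress = (epoch - cfg.warmup_epochs) / span
        base = cfg.base_lr * 0.5 * (1.0 + math.cos(math.pi * progress))
    return base, base * cfg.head_lr_multiplier


def ema_update(ema: dict[str, np.ndarray], raw: dict[str, np.ndarray],
               decay: float) -> dict[str, np.ndarray]:
    """In-place ``ema <- decay * ema + (1 - decay) * raw``, elementwise."""
    if set(ema) != set(raw):
        raise ValueError("EMA/raw parameter structures differ")
    for k in ema:
        if ema[k].shape != raw[k].shape:
            raise ValueError(f"EMA/raw shape mismatch for {k}")
        ema[k] *= decay
        ema[k] += (1.0 - decay) * raw[k]
    return ema


class ImageStore:
    """Maps manifest image names to 2-D intensity arrays.

    Either backed by a directory of image files (lazy, cached) or by a
    preloaded dict — the latter lets tests skip disk entirely.
    """

    def __init__(self, root=None, arrays: dict[str, np.ndarray] | None = None):
        self.root = Path(root) if root is not None else None
        self.cache: dict[str, np.ndarray] = dict(arrays or {})

    def get(self, name: str) -> np.ndarray:
        if name not in self.cache:
            if self.root is None:
                raise KeyError(f"image {name!r} not preloaded and no root set")
            self.cache[name] = load_image(self.root / name)
        return self.cache[name]


@dataclass
class TrainState:
    epoch_log: pd.DataFrame
    best_val_qwk: float
    best_epoch: int
    best_weights: dict[str, np.ndarray]
    best_is_ema: bool
    raw_weights: dict[str, np.ndarray]
    ema_weights: dict[str, np.ndarray]
    config: TrainConfig


def _eval_split(
    model: FusionModel,
    bundles: list,
    grades: np.ndarray,
    weights: LossWeights,
    sigma: float,
    batch_size: int,
) -> tuple[float, float, float]:
    """(loss, accuracy, qwk) on a fixed list of eval bundles."""
    losses, preds = [], []
    n_ld = model.heads["ld"].weight.value.shape[0]
    from .model import merge_grades

    y_eval = merge_grades(grades) if n_ld == 4 else grades
    for i in range(0, len(bundles), batch_size):
        batch = bundles[i : i + batch_size]
        yb = grades[i : i + batch_size]
        out, _ = model.forward(batch, train=False)
        loss, _, _ = composite_loss(out, yb, weights, sigma)
        losses.append(loss * len(batch))
        preds.append(out.ld_logits.argmax(axis=1))
    preds = np.concatenate(preds)
    acc = float(np.mean(preds == y_eval))
    kappa = qwk(y_eval, preds, n_classes=n_ld)
    return float(np.sum(losses) / len(bundles)), acc, kappa


def fit(
    model: FusionModel,
    train_manifest: CohortManifest,
    val_manifest: CohortManifest,
    images: ImageStore,
    config: TrainConfig = TrainConfig(),
) -> TrainState:
    """Train with the composite loss; select on validation QWK.

    Per epoch: seeded-shuffled minibatches with (optionally) augmented
    bundles; AdamW step with the scheduled rates; EMA update per step.  At
    epoch end the validation split is scored (loss, accuracy from the
    distribution head's argmax, and QWK); improvement snapshots raw and EMA
    weights and resets the patience counter.  Deterministic under
    ``config.seed``.
    """
    cfg = config.resolved()
    if len(train_manifest) == 0 or len(val_manifest) == 0:
        raise ValueError("empty training or validation split")
    rng = np.random.default_rng(cfg.seed)
    size = model.config.image_size
    patch = model.config.patch_size
    policy = AugmentPolicy(enabled=cfg.augment)

    train_names = train_manifest.frame["image"].to_numpy()
    train_grades = train_manifest.frame["kl_grade"].to_numpy(dtype=int)
    val_grades = val_manifest.frame["kl_grade"].to_numpy(dtype=int)
    val_bundles = [
        eval_bundle(images.get(n), size, patch)
        for n in val_manifest.frame["image"]
    ]
    if not cfg.augment:
        fixed = {
            n: eval_bundle(images.get(n), size, patch) for n in train_names
        }

    optimizer = nn.AdamW(
        [
            {"params": model.backbone_params(), "lr": cfg.base_lr,
             "weight_decay": cfg.weight_decay},
            {"params": model.head_params(),
             "lr": cfg.base_lr * cfg.head_lr_multiplier,
             "weight_decay": cfg.weight_decay},
        ]
    )
    ema = {k: v.copy() for k, v in model.state_dict().items()}

    from .model import merge_grades

    n_ld = model.heads["ld"].weight.value.shape[0]
    best_qwk, best_epoch, since = -np.inf, -1, 0
    best_raw = best_ema = None
    log_rows = []
    for epoch in range(cfg.max_epochs):
        lr_b, lr_h = lr_at(epoch, cfg)
        optimizer.groups[0]["lr"] = lr_b
        optimizer.groups[1]["lr"] = lr_h
        order = rng.permutation(len(train_names))
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            sel = order[i : i + cfg.batch_size]
            yb = train_grades[sel]
            if cfg.augment:
                batch = [
                    apply_augment(images.get(train_names[j]), policy, rng,
                                  size, patch)
                    for j in sel
                ]
            else:
                batch = [fixed[train_names[j]] for j in sel]
            out, cache = model.forward(batch, train=True, rng=rng)
            loss, _, grads = composite_loss(out, yb, cfg.loss_weights, cfg.sigma)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss}"
                )
            optimizer.zero_grad()
            model.backward(grads, cache)
            optimizer.step()
            # GeM exponents must stay >= 1 for a valid generalized mean
            for pool in (model.global_pool, model.patch_pool):
                if pool is not None:
                    pool.p.value = np.maximum(pool.p.value, 1.0)
            ema_update(ema, model.state_dict(), cfg.ema_decay)
            ep_loss += loss * len(sel)
            y_cmp = merge_grades(yb) if n_ld == 4 else yb
            ep_correct += int((out.ld_logits.argmax(axis=1) == y_cmp).sum())

        train_loss = ep_loss / len(order)
        train_acc = ep_correct / len(order)
        val_loss, val_acc, val_qwk = _eval_split(
            model, val_bundles, val_grades, cfg.loss_weights, cfg.sigma,
            cfg.batch_size,
        )
        improved = val_qwk > best_qwk
        if improved:
            best_qwk, best_epoch, since = val_qwk, epoch, 0
            best_raw = model.state_dict()
            best_ema = {k: v.copy() for k, v in ema.items()}
        else:
            since += 1
        log_rows.append(
            dict(epoch=epoch, train_loss=train_loss, train_acc=train_acc,
                 val_loss=val_loss, val_acc=val_acc, val_qwk=val_qwk,
                 best_val_qwk=best_qwk, lr_backbone=lr_b, lr_head=lr_h)
        )
        if since >= cfg.patience:
            break

    # model selection: raw vs EMA snapshot, better validation QWK wins
    model.load_state_dict(best_ema)
    _, _, qwk_ema = _eval_split(
        model, val_bundles, val_grades, cfg.loss_weights, cfg.sigma, cfg.batch_size
    )
    best_is_ema = qwk_ema >= best_qwk
    best_weights = best_ema if best_is_ema else best_raw
    selected_qwk = max(qwk_ema, best_qwk)
    model.load_state_dict(best_weights)
    return TrainState(
        epoch_log=pd.DataFrame(log_rows),
        best_val_qwk=float(selected_qwk),
        best_epoch=best_epoch,
        best_weights=best_weights,
        best_is_ema=bool(best_is_ema),
        raw_weights=best_raw,
        ema_weights=best_ema,
        config=cfg,
    )


# -- checkpoints ---------------------------------------------------------

def save_checkpoint(
    path,
    model: FusionModel,
    state: TrainState | None = None,
    cutpoints: Cutpoints | None = None,
    cutpoint_partition: str | None = None,
) -> None:
    """Persist weights, EMA weights, config, cutpoints, seed and val QWK."""
    meta = {
        "model_config": vars(model.config).copy(),
        "cutpoints": list(cutpoints.values) if cutpoints else None,
        "cutpoint_partition": cutpoint_partition,
        "seed": state.config.seed if state else model.config.seed,
        "best_epoch": state.best_epoch if state else None,
        "val_qwk": state.best_val_qwk if state else None,
        "best_is_ema": state.best_is_ema if state else None,
    }
    arrays = {f"w::{k}": v for k, v in model.state_dict().items()}
    if state is not None:
        arrays.update({f"ema::{k}": v for k, v in state.ema_weights.items()})
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path) -> tuple[FusionModel, dict]:
    """Rebuild the model (selected weights loaded) plus the metadata dict."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        weights = {k[3:]: z[k] for k in z.files if k.startswith("w::")}
        ema = {k[5:]: z[k] for k in z.files if k.startswith("ema::")}
    model = build_model(ModelConfig(**meta["model_config"]))
    model.load_state_dict(weights)
    meta["ema_weights"] = ema
    if meta.get("cutpoints"):
        meta["cutpoints"] = Cutpoints(tuple(meta["cutpoints"]))
    return model, meta


def finetune(
    model: FusionModel,
    train_manifest: CohortManifest,
    val_manifest: CohortManifest,
    images: ImageStore,
    config: TrainConfig | None = None,
) -> TrainState:
    """Adapt a trained model to a new domain (all parameters unfrozen).

    Uses the fine-tuning rate/patience/epoch overrides and the same
    composite loss.  With ``max_epochs`` overridden to 0 the input weights
    are returned unchanged.
    """
    cfg = config or TrainConfig(finetune=True)
    if not cfg.finetune:
        cfg = replace(cfg, finetune=True)
    if cfg.resolved().max_epochs == 0:
        w = model.state_dict()
        return TrainState(
            epoch_log=pd.DataFrame(), best_val_qwk=float("nan"), best_epoch=-1,
            best_weights=w, best_is_ema=False, raw_weights=w,
            ema_weights={k: v.copy() for k, v in w.items()}, config=cfg.resolved(),
        )
    return fit(model, train_manifest, val_manifest, images, cfg)
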