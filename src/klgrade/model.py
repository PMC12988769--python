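"""The three-stream ordinal grading network.

A global encoder sees the whole joint; one *shared* patch encoder sees the
left and right midline halves (two forward passes through the same
parameters).  Spatial feature maps are pooled with learnable generalized-
mean (GeM) pooling, the three embeddings are concatenated, passed through
Dropout(0.1), L2-normalized, and fed to three linear heads:

* ordinal head — 4 logits for the cumulative targets 1[y > k], k = 0..3;
* label-distribution head — 5 logits trained against a Gaussian-smoothed
  grade distribution;
* binary head — 1 logit for clinically significant disease (KL >= 2).

Encoders are pluggable: anything mapping a 3xSxS batch to either a feature
vector or a Dxhxw map satisfies the contract, so tests run with tiny conv
stacks while large named backbones remain a configuration choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import nn
from .preprocess import ViewBundle

#: encoder registry: name -> (constructor | None for stubs)
KNOWN_ENCODERS = ("tiny", "tiny16", "convnext_base", "resnet50", "nfnet_f4")
_STUB_ENCODERS = {"convnext_base", "resnet50", "nfnet_f4"}

HEAD_SETS = ("multitask", "flat5c", "dualhead4c")


@dataclass
class HeadOutputs:
    """Raw head outputs for a batch."""

    ordinal_logits: np.ndarray | None  # (B, 4)
    ld_logits: np.ndarray  # (B, 5) or (B, 4) for the merged variant
    binary_logit: np.ndarray | None  # (B,)


def gem_pool(feature_map: np.ndarray, p: float = 3.0, eps: float = 1e-6) -> np.ndarray:
    """Generalized-mean pool a Dxhxw (or BxDxhxw) map to a vector.

    Per channel: ``(mean clamp(x, eps)^p)^(1/p)``.  p=1 is average pooling;
    p -> inf approaches max pooling.
    """
    if p < 1.0 or p <= 0:
        raise ValueError("GeM exponent p must be >= 1")
    x = np.asarray(feature_map, dtype=np.float64)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    xc = np.maximum(x, eps)
    y = ((xc**p).mean(axis=(2, 3))) ** (1.0 / p)
    return y[0] if squeeze else y


class TinyConvEncoder(nn.Sequential):
    """Small strided conv stack for desk-scale experiments.

    Three 3x3 stride-2 conv+ReLU blocks; emits a spatial map for GeM pooling
    (and Grad-CAM).  ``feature_dim`` is the channel count of the last conv.
    """

    def __init__(self, feature_dim: int = 32, rng=None, name="enc"):
        rng = rng or np.random.default_rng(0)
        c1, c2 = max(4, feature_dim // 4), max(8, feature_dim // 2)
        super().__init__(
            nn.Conv2d(3, c1, 3, stride=2, pad=1, rng=rng, name=f"{name}.c1"),
            nn.ReLU(),
            nn.Conv2d(c1, c2, 3, stride=2, pad=1, rng=rng, name=f"{name}.c2"),
            nn.ReLU(),
            nn.Conv2d(c2, feature_dim, 3, stride=2, pad=1, rng=rng, name=f"{name}.c3"),
            nn.ReLU(),
        )
        self.feature_dim = feature_dim

    @property
    def last_conv_index(self) -> int:
        """Index of the last conv layer's ReLU output (Grad-CAM hook point)."""
        return len(self.layers) - 1


def _make_encoder(name: str, feature_dim: int, rng, prefix: str) -> TinyConvEncoder:
    if name in _STUB_ENCODERS:
        raise ValueError(
            f"encoder '{name}' is a configuration stub for large pretrained "
            f"backbones and is not bundled; available here: tiny, tiny16"
        )
    if name == "tiny":
        return TinyConvEncoder(feature_dim=feature_dim, rng=rng, name=prefix)
    if name == "tiny16":
        return TinyConvEncoder(feature_dim=16, rng=rng, name=prefix)
    raise ValueError(f"unknown encoder '{name}'; choices: {KNOWN_ENCODERS}")


@dataclass
class ModelConfig:
    """Architecture configuration (see also the named presets)."""

    global_encoder: str = "tiny"
    patch_encoder: str = "tiny"
    head_set: str = "multitask"  # multitask | flat5c | dualhead4c
    feature_dim: int = 32
    image_size: int = 64
    patch_size: int = 64
    dropout: float = 0.1
    gem_p_init: float = 3.0
    gem_eps: float = 1e-6
    use_patches: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        if self.head_set not in HEAD_SETS:
            raise ValueError(f"unknown head_set '{self.head_set}'; choices: {HEAD_SETS}")
        if self.head_set == "flat5c":
            self.use_patches = False

    @property
    def n_classes(self) -> int:
        return 4 if self.head_set == "dualhead4c" else 5


def merge_grades(y: np.ndarray) -> np.ndarray:
    """Map KL grades 0..4 to the merged label space {0&1, 2, 3, 4} -> 0..3."""
    y = np.asarray(y)
    return np.maximum(y - 1, 0)


class FusionModel:
    """Three-stream multitask network (or its single-stream ablations)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.global_encoder = _make_encoder(
            config.global_encoder, config.feature_dim, rng, prefix="genc"
        )
        self.global_pool = nn.GeMPool(config.gem_p_init, config.gem_eps, name="gem_g")
        if config.use_patches:
            self.patch_encoder = _make_encoder(
                config.patch_encoder, config.feature_dim, rng, prefix="penc"
            )
            self.patch_pool = nn.GeMPool(config.gem_p_init, config.gem_eps, name="gem_p")
        else:
            self.patch_encoder = None
            self.patch_pool = None
        d = self.global_encoder.feature_dim
        fused = d + (2 * self.patch_encoder.feature_dim if self.patch_encoder else 0)
        self.fused_dim = fused
        self.dropout = nn.Dropout(config.dropout)

        self.heads: dict[str, nn.Linear] = {}
        if config.head_set == "multitask":
            self.heads["ordinal"] = nn.Linear(fused, 4, rng=rng, name="head_ord")
            self.heads["ld"] = nn.Linear(fused, 5, rng=rng, name="head_ld")
            self.heads["binary"] = nn.Linear(fused, 1, rng=rng, name="head_bin")
        elif config.head_set == "flat5c":
            self.heads["ld"] = nn.Linear(fused, 5, rng=rng, name="head_ld")
        else:  # dualhead4c: 4-class distribution head + binary severity head
            self.heads["ld"] = nn.Linear(fused, 4, rng=rng, name="head_ld")
            self.heads["binary"] = nn.Linear(fused, 1, rng=rng, name="head_bin")

    # -- parameter groups ------------------------------------------------
    def backbone_params(self) -> list[nn.Param]:
        params = self.global_encoder.params() + self.global_pool.params()
        if self.patch_encoder is not None:
            params += self.patch_encoder.params() + self.patch_pool.params()
        return params

    def head_params(self) -> list[nn.Param]:
        return [p for head in self.heads.values() for p in head.params()]

    def params(self) -> list[nn.Param]:
        return self.backbone_params() + self.head_params()

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    # -- weight state ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.params()}
        assert len(state) == len(self.params()), "parameter name collision"
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {p.name: p for p in self.params()}
        if set(own) != set(state):
            raise ValueError("parameter structure mismatch in state dict")
        for name, p in own.items():
            if p.value.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.value = state[name].copy()

    # -- forward / backward ----------------------------------------------
    def _stack(self, bundles: list[ViewBundle], attr: str) -> np.ndarray:
        return np.stack([getattr(b, attr) for b in bundles])

    def forward(
        self, bundles: list[ViewBundle], train: bool = False, rng=None
    ) -> tuple[HeadOutputs, dict]:
        """Run a batch of bundles; returns outputs and the backward cache."""
        xg = self._stack(bundles, "global_view")
        gmap, c_genc = self.global_encoder.forward(xg, train=train, rng=rng)
        gvec, c_gpool = self.global_pool.forward(gmap, train=train)
        embeds = [gvec]
        cache: dict = {
            "genc": c_genc,
            "gpool": c_gpool,
            "gmap": gmap,
            "dims": [gvec.shape[1]],
        }
        if self.patch_encoder is not None:
            xl = self._stack(bundles, "left_patch")
            xr = self._stack(bundles, "right_patch")
            lmap, c_lenc = self.patch_encoder.forward(xl, train=train, rng=rng)
            lvec, c_lpool = self.patch_pool.forward(lmap, train=train)
            rmap, c_renc = self.patch_encoder.forward(xr, train=train, rng=rng)
            rvec, c_rpool = self.patch_pool.forward(rmap, train=train)
            embeds += [lvec, rvec]
            cache.update(
                lenc=c_lenc, lpool=c_lpool, renc=c_renc, rpool=c_rpool,
                lmap=lmap, rmap=rmap,
            )
            cache["dims"] += [lvec.shape[1], rvec.shape[1]]
        fused = np.concatenate(embeds, axis=1)
        dropped, c_drop = self.dropout.forward(fused, train=train, rng=rng)
        normed, c_norm = nn.l2_normalize(dropped)
        cache.update(drop=c_drop, norm=c_norm)

        head_out: dict[str, np.ndarray] = {}
        cache["heads"] = {}
        for name, head in self.heads.items():
            y, c = head.forward(normed, train=train)
            head_out[name] = y
            cache["heads"][name] = c
        outputs = HeadOutputs(
            ordinal_logits=head_out.get("ordinal"),
            ld_logits=head_out["ld"],
            binary_logit=head_out["binary"][:, 0] if "binary" in head_out else None,
        )
        return outputs, cache

    def backward(self, grads: dict[str, np.ndarray], cache: dict) -> None:
        """Backpropagate head-output gradients; accumulates into Param.grad.

        ``grads`` maps head name -> dLoss/dlogits with the head's output
        shape (binary as (B,) or (B,1)).
        """
        dnorm = None
        for name, head in self.heads.items():
            if name not in grads:
                continue
            g = np.asarray(grads[name], dtype=np.float64)
            if g.ndim == 1:
                g = g[:, None]
            dx = head.backward(g, cache["heads"][name])
            dnorm = dx if dnorm is None else dnorm + dx
        if dnorm is None:
            raise ValueError("no head gradients supplied")
        ddrop = nn.l2_normalize_backward(dnorm, cache["norm"])
        dfused = self.dropout.backward(ddrop, cache["drop"])
        dims = cache["dims"]
        dg = dfused[:, : dims[0]]
        dgmap = self.global_pool.backward(dg, cache["gpool"])
        self.global_encoder.backward(dgmap, cache["genc"])
        if self.patch_encoder is not None:
            off = dims[0]
            dl = dfused[:, off : off + dims[1]]
            dr = dfused[:, off + dims[1] :]
            dlmap = self.patch_pool.backward(dl, cache["lpool"])
            drmap = self.patch_pool.backward(dr, cache["rpool"])
            # shared encoder: two backward passes accumulate into one
            # parameter set
            self.patch_encoder.backward(dlmap, cache["lenc"])
            self.patch_encoder.backward(drmap, cache["renc"])


def build_model(config: ModelConfig | dict) -> FusionModel:
    """Construct a model from a config (dataclass or plain mapping)."""
    if isinstance(config, dict):
        config = ModelConfig(**config)
    return FusionModel(config)


#: named presets mirroring the compared training configurations; the large
#: pretrained variants are stubs that fail fast with a clear message
MODEL_PRESETS: dict[str, dict] = {
    "tiny_multitask": dict(global_encoder="tiny", patch_encoder="tiny",
                           head_set="multitask"),
    "flat5c_global": dict(global_encoder="tiny", head_set="flat5c",
                          use_patches=False),
    "dualhead4c": dict(global_encoder="tiny", patch_encoder="tiny",
                       head_set="dualhead4c"),
    "fusenet_full": dict(global_encoder="convnext_base", patch_encoder="resnet50",
                         head_set="multitask", image_size=224, patch_size=224),
    "flat5c_nfnetf4": dict(global_encoder="nfnet_f4", head_set="flat5c",
                           use_patches=False, image_size=384, patch_size=384),
}


def build_preset(name: str, **overrides) -> FusionModel:
    if name not in MODEL_PRESETS:
        raise ValueError(f"unknown preset '{name}'; choices: {sorted(MODEL_PRESETS)}")
    cfg = {**MODEL_PRESETS[name], **overrides}
    return build_model(ModelConfig(**cfg))


def parameter_count(model: FusionModel) -> int:
    return int(sum(p.value.size for p in model.params()))
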