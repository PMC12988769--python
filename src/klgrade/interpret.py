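"""Grad-CAM heatmaps from the label-distribution head.

The class-activation map for a stream is the rectified, gradient-weighted
sum of that stream's last convolutional activation channels, where the
channel weights are the spatial means of the gradients of the predicted
class's distribution-head logit.  Maps are min-max normalized to [0, 1]
(constant maps are defined as all zeros) and bilinearly upsampled to the
input size for overlay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from PIL import Image

from . import nn
from .model import FusionModel
from .preprocess import ViewBundle, _resize


@dataclass
class Heatmap:
    values: np.ndarray  # 2-D in [0, 1], input-sized
    source_stream: str  # "global" or "patch"
    target_class: int
    overlay_alpha: float = 0.35


def gradcam(model: FusionModel, bundle: ViewBundle, stream: str = "global") -> Heatmap:
    """Class-activation map for one bundle through one encoder stream.

    The target is the distribution-head logit of its argmax class; the
    gradient is taken at the stream's last conv activation (the encoder's
    spatial output), never updating any weights.
    """
    if stream not in ("global", "patch"):
        raise ValueError("stream must be 'global' or 'patch'")
    if stream == "patch" and model.patch_encoder is None:
        raise ValueError("this configuration has no patch stream")
    outputs, cache = model.forward([bundle], train=False)
    target_class = int(outputs.ld_logits[0].argmax())

    # backprop d(logit_target)/d(activations); never touches Param.grad
    dld = np.zeros_like(outputs.ld_logits)
    dld[0, target_class] = 1.0
    dnorm = dld @ model.heads["ld"].weight.value
    ddrop = nn.l2_normalize_backward(dnorm, cache["norm"])
    dfused = model.dropout.backward(ddrop, cache["drop"])
    dims = cache["dims"]
    if stream == "global":
        dvec = dfused[:, : dims[0]]
        dmap = model.global_pool.backward_input(dvec, cache["gpool"])
        fmap = cache["gmap"][0]
        ref = bundle.global_view
    else:
        off = dims[0]
        dvec = dfused[:, off : off + dims[1]]
        dmap = model.patch_pool.backward_input(dvec, cache["lpool"])
        fmap = cache["lmap"][0]
        ref = bundle.left_patch

    grads = dmap[0]  # (D, h, w)
    weights = grads.mean(axis=(1, 2))  # spatial-mean channel weights
    cam = np.maximum((weights[:, None, None] * fmap).sum(axis=0), 0.0)
    lo, hi = cam.min(), cam.max()
    if hi - lo < 1e-12:
        cam = np.zeros_like(cam)
    else:
        cam = (cam - lo) / (hi - lo)
    size = ref.shape[-1]
    cam = np.clip(_resize(cam, (ref.shape[-2], size)), 0.0, 1.0)
    return Heatmap(values=cam, source_stream=stream, target_class=target_class)


def overlay(image: np.ndarray, heatmap: Heatmap | np.ndarray,
            alpha: float = 0.35, cmap: str = "jet") -> np.ndarray:
    """Alpha-blend a colormapped heatmap over a grayscale image.

    ``image`` is 2-D in [0, 255]; returns an HxWx3 uint8 array (PNG-ready).
    alpha=0 reproduces the input, alpha=1 the pure colormap.
    """
    values = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    img = np.asarray(image, dtype=np.float64)
    if img.shape != values.shape:
        raise ValueError("image and heatmap sizes must match")
    base = np.repeat(img[:, :, None], 3, axis=2) / 255.0
    colored = colormaps[cmap](values)[:, :, :3]
    blended = (1.0 - alpha) * base + alpha * colored
    return np.clip(np.round(blended * 255.0), 0, 255).astype(np.uint8)


def save_overlay(path, image: np.ndarray, heatmap: Heatmap,
                 alpha: float = 0.35) -> None:
    Image.fromarray(overlay(image, heatmap, alpha), mode="RGB").save(path)
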