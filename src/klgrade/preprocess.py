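"""Deletterboxing, standardization, midline patches, augmentation and TTA.

Every model input is a :class:`ViewBundle`: the full joint ("global" view)
plus the left and right halves cut at the vertical midline, all carried
through one shared transform realization so the three streams stay
spatially consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])

BAR_FRACTION = 0.995  # a border line is a bar when >=99.5% pixels are extreme
NEAR_BLACK = 8.0
NEAR_WHITE = 247.0
TTA_ROTATIONS = (3.0, -3.0, 5.0, -5.0, 7.0, -7.0)


def _is_bar(line: np.ndarray) -> bool:
    extreme = (line < NEAR_BLACK) | (line > NEAR_WHITE)
    return extreme.mean() >= BAR_FRACTION


def deletterbox(image: np.ndarray) -> np.ndarray:
    """Trim solid black/white export bars from all four borders.

    Scans inward row by row (and column by column) from each side, trimming
    while the next line is >=99.5% near-black (<8) or near-white (>247), and
    stops before the output would fall below 50% of the original height or
    width on that axis.  Bar-free images come back unchanged (idempotent).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("deletterbox expects a nonempty 2-D image")
    h, w = img.shape
    min_h, min_w = (h + 1) // 2, (w + 1) // 2

    top, bot = 0, h
    while bot - top > min_h and _is_bar(img[top, :]):
        top += 1
    while bot - top > min_h and _is_bar(img[bot - 1, :]):
        bot -= 1
    left, right = 0, w
    while right - left > min_w and _is_bar(img[top:bot, left]):
        left += 1
    while right - left > min_w and _is_bar(img[top:bot, right - 1]):
        right -= 1
    return img[top:bot, left:right]


def _resize(image: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of a 2-D float array to (height, width)."""
    im = Image.fromarray(np.asarray(image, dtype=np.float32), mode="F")
    out = im.resize((size[1], size[0]), resample=Image.BILINEAR)
    return np.asarray(out, dtype=np.float64)


def normalize(rgb: np.ndarray) -> np.ndarray:
    """Scale a 3xHxW array from [0,255] to ImageNet-normalized units."""
    x = rgb / 255.0
    return (x - IMAGENET_MEAN[:, None, None]) / IMAGENET_STD[:, None, None]


def denormalize(x: np.ndarray) -> np.ndarray:
    return (x * IMAGENET_STD[:, None, None] + IMAGENET_MEAN[:, None, None]) * 255.0


def standardize(image: np.ndarray, size: int = 224) -> np.ndarray:
    """Deletterboxed 2-D image -> normalized 3xSxS array.

    Bilinear resize to SxS, grayscale replicated across 3 channels (the
    encoders expect RGB), then per-channel ImageNet mean/std normalization.
    """
    resized = _resize(image, (size, size))
    rgb = np.repeat(resized[None, :, :], 3, axis=0)
    return normalize(rgb)


def midline_patches(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cut an image (2-D HxW or 3-D CxHxW) at the vertical midline.

    Left = columns [0, floor(W/2)), right = the remainder; for odd widths the
    right half keeps the extra column.  The unresized halves tile the input.
    """
    w = image.shape[-1]
    if w < 2:
        raise ValueError("image too narrow to split at the midline")
    mid = w // 2
    return image[..., :mid], image[..., mid:]


@dataclass(frozen=True)
class ViewBundle:
    """The triplet of inputs for one radiograph, identically transformed."""

    global_view: np.ndarray  # 3 x S x S
    left_patch: np.ndarray  # 3 x P x P
    right_patch: np.ndarray  # 3 x P x P

    def __post_init__(self) -> None:
        if self.left_patch.shape != self.right_patch.shape:
            raise ValueError("patch views must share a spatial size")


@dataclass(frozen=True)
class AugmentPolicy:
    """Training-time geometric/photometric augmentation ranges."""

    hflip_prob: float = 0.5
    rotation_deg: float = 8.0
    crop_scale: tuple[float, float] = (0.88, 1.0)
    crop_aspect: tuple[float, float] = (0.9, 1.1)
    jitter: float = 0.08  # brightness/contrast half-range
    enabled: bool = True


def _resize_patch(half: np.ndarray, patch_size: int) -> np.ndarray:
    return np.stack([_resize(c, (patch_size, patch_size)) for c in half])


def _bundle_from_global(global_view: np.ndarray, patch_size: int) -> ViewBundle:
    left, right = midline_patches(global_view)
    return ViewBundle(
        global_view=global_view,
        left_patch=_resize_patch(left, patch_size),
        right_patch=_resize_patch(right, patch_size),
    )


def eval_bundle(image: np.ndarray, size: int = 224, patch_size: int | None = None) -> ViewBundle:
    """Deterministic evaluation-time bundle: deletterbox -> standardize -> cut."""
    patch_size = patch_size or size
    g = standardize(deletterbox(image), size)
    return _bundle_from_global(g, patch_size)


def apply_augment(
    image: np.ndarray,
    policy: AugmentPolicy,
    rng: np.random.Generator,
    size: int = 224,
    patch_size: int | None = None,
    training: bool = True,
) -> ViewBundle:
    """One stochastic training bundle, with a single shared realization.

    The flip decision, rotation angle, resized-crop window and jitter are
    sampled once and applied to the global image; the midline patches are
    then cut from the *augmented* global view, so all three streams see the
    same realization.  Order: flip -> rotate -> resized-crop -> jitter ->
    normalize.
    """
    if policy.enabled and not training:
        raise RuntimeError("augmentation policy must be disabled at eval time")
    patch_size = patch_size or size
    img = deletterbox(image)
    if not policy.enabled:
        return _bundle_from_global(standardize(img, size), patch_size)

    h, w = img.shape
    if rng.random() < policy.hflip_prob:
        img = img[:, ::-1]
    angle = rng.uniform(-policy.rotation_deg, policy.rotation_deg)
    img = rotate(img, angle)

    scale = rng.uniform(*policy.crop_scale)
    aspect = rng.uniform(*policy.crop_aspect)
    area = scale * h * w
    cw = min(w, int(round(np.sqrt(area * aspect))))
    ch = min(h, int(round(np.sqrt(area / aspect))))
    y0 = int(rng.integers(0, h - ch + 1))
    x0 = int(rng.integers(0, w - cw + 1))
    img = img[y0 : y0 + ch, x0 : x0 + cw]

    brightness = 1.0 + rng.uniform(-policy.jitter, policy.jitter)
    contrast = 1.0 + rng.uniform(-policy.jitter, policy.jitter)
    mean = img.mean()
    img = np.clip((img * brightness - mean) * contrast + mean, 0.0, 255.0)

    return _bundle_from_global(standardize(img, size), patch_size)


def rotate(image: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a 2-D image about its center, bilinear, black fill."""
    im = Image.fromarray(np.asarray(image, dtype=np.float32), mode="F")
    out = im.rotate(angle_deg, resample=Image.BILINEAR, fillcolor=0.0)
    return np.asarray(out, dtype=np.float64)


def tta_views(
    image: np.ndarray, size: int = 224, patch_size: int | None = None, tta: int = 8
) -> list[ViewBundle]:
    """Deterministic test-time augmentation bundles.

    ``tta=8``: identity, horizontal flip, rotations +-3, +-5, +-7 degrees.
    ``tta=4``: identity, flip, +-5 degrees.  ``tta<=1``: identity only.
    Each transform acts on the deletterboxed global image before patch
    extraction, so the three streams stay aligned.
    """
    patch_size = patch_size or size
    img = deletterbox(image)
    transforms: list[np.ndarray] = [img]
    if tta >= 2:
        transforms.append(img[:, ::-1])
    if tta >= 8:
        rots = TTA_ROTATIONS
    elif tta >= 4:
        rots = (5.0, -5.0)
    else:
        rots = ()
    transforms.extend(rotate(img, a) for a in rots)
    return [
        _bundle_from_global(standardize(t, size), patch_size) for t in transforms
    ]
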