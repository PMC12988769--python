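"""Procedural radiograph-like cohorts with a known ordinal severity signal.

The generator emulates the *structure* of a bilateral knee-radiograph cohort
— composite ``{patient_id}{L|R}`` naming, per-patient grade pairs, cohort
grade marginals — and renders images carrying a monotone ordinal cue
analogous to the radiographic hallmarks of osteoarthritis:

* two bright horizontal "bone" bands separated by a dark joint-space gap
  whose width shrinks linearly with grade (joint-space narrowing),
* bright blobs at the band margins whose count grows with grade
  (osteophytes),
* a brightening strip under the joint line whose intensity grows with grade
  (subchondral sclerosis).

None of this is anatomically realistic; it exists so that every downstream
stage (splitting, training, decoding, evaluation, adaptation) is exercisable
and testable without any real data.  An optional "external" domain-shift
mode applies a fixed brightness offset, contrast scale and a higher
letterbox probability, giving the fine-tuning protocol a genuine
distribution change to adapt to.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .manifest import CohortManifest, MANIFEST_COLUMNS

#: cohort-level KL-grade marginals of a large bilateral osteoarthritis
#: screening population (grade 0 most common, grade 4 rare)
DEFAULT_MARGINALS = (0.394, 0.181, 0.263, 0.131, 0.031)

# fixed photometric offsets applied in domain_shift="external" mode
EXTERNAL_BRIGHTNESS_OFFSET = 25.0
EXTERNAL_CONTRAST_SCALE = 0.85
EXTERNAL_LETTERBOX_PROB = 0.8


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    ``gap_base`` and ``gap_step`` are in pixels at the rendered
    ``image_size``: a grade-g joint gap is ``gap_base - g * gap_step`` wide
    (plus noise), so ``gap_base - 4*gap_step`` must stay positive.
    """

    n_patients: int = 100
    bilateral: bool = True
    grade_marginals: tuple[float, ...] = DEFAULT_MARGINALS
    image_size: int = 224
    gap_base: float = 60.0  # joint-space width in pixels at grade 0
    gap_step: float = 11.0  # pixels of joint space lost per grade
    noise_sd: float = 8.0
    letterbox_prob: float = 0.0
    domain_shift: str = "none"
    seed: int = 42

    def __post_init__(self) -> None:
        m = np.asarray(self.grade_marginals, dtype=float)
        if len(m) != 5 or (m < 0).any():
            raise ValueError("grade_marginals must be 5 nonnegative probabilities")
        if abs(m.sum() - 1.0) > 1e-9:
            raise ValueError("grade_marginals must sum to 1")
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32")
        if self.gap_px(4) <= 0:
            raise ValueError("gap_base - 4*gap_step must remain positive")
        if self.domain_shift not in ("none", "external"):
            raise ValueError("domain_shift must be 'none' or 'external'")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")

    def gap_px(self, grade: int) -> float:
        """Noise-free joint-gap width in pixels for a grade."""
        return self.gap_base - grade * self.gap_step

    @property
    def effective_letterbox_prob(self) -> float:
        if self.domain_shift == "external":
            return max(self.letterbox_prob, EXTERNAL_LETTERBOX_PROB)
        return self.letterbox_prob


@dataclass
class RenderedImage:
    pixels: np.ndarray  # 2-D uint8-range intensities
    true_grade: int
    patient_id: str
    laterality: str = "none"


def _sample_grades(rng: np.random.Generator, marginals, size: int) -> np.ndarray:
    return rng.choice(5, size=size, p=np.asarray(marginals, dtype=float))


def generate_roster(spec: SyntheticSpec) -> CohortManifest:
    """Sample a patient roster (no images yet) following the spec.

    Bilateral cohorts draw one *maximum* grade per patient from the grade
    marginals and assign it to a uniformly chosen knee; the other knee gets
    a uniform grade in ``0..max``.  The per-patient max grade — the
    stratification variable of the splitter — therefore follows the
    marginals exactly.  Single-image cohorts draw each patient's grade
    directly from the marginals.
    """
    rng = np.random.default_rng(spec.seed)
    width = max(4, len(str(spec.n_patients)))
    pids = [f"9{str(i).zfill(width)}" for i in range(spec.n_patients)]
    cohort = "external" if spec.domain_shift == "external" else "internal"
    rows = []
    max_grades = _sample_grades(rng, spec.grade_marginals, spec.n_patients)
    if spec.bilateral:
        for pid, gmax in zip(pids, max_grades):
            other = int(rng.integers(0, gmax + 1))
            if rng.random() < 0.5:
                gl, gr = int(gmax), other
            else:
                gl, gr = other, int(gmax)
            rows.append((f"{pid}L.png", pid, "L", gl, cohort))
            rows.append((f"{pid}R.png", pid, "R", gr, cohort))
    else:
        for pid, g in zip(pids, max_grades):
            rows.append((f"{pid}.png", pid, "none", int(g), cohort))
    frame = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return CohortManifest(frame)


def render_image(
    grade: int, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    """Render one radiograph-like image for a grade; returns 2-D float array.

    The severity cue is deterministic given (grade, rng state): gap width
    ``gap_base - grade*gap_step`` plus Gaussian jitter, ``2*grade`` marginal
    osteophyte blobs, and a sclerosis strip of intensity ``30*grade/4``.
    """
    if not 0 <= int(grade) <= 4:
        raise ValueError("grade must be in 0..4")
    grade = int(grade)
    s = spec.image_size
    img = np.full((s, s), 30.0)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=(s, s))
        center = s / 2 + rng.normal(0, s * 0.01)
        gap = spec.gap_px(grade) + rng.normal(0, spec.noise_sd * 0.1)
    else:
        center = s / 2
        gap = spec.gap_px(grade)
    # lay the gap down as an exact integer row count so the noise-free cue
    # is measurable to the pixel
    gap_rows = max(2, int(round(gap)))
    band_h = max(2, int(s * 0.22))
    top_hi = int(round(center - gap_rows / 2))
    bot_lo = top_hi + gap_rows
    img[max(0, top_hi - band_h) : max(0, top_hi), :] += 160.0
    img[max(0, bot_lo) : min(s, bot_lo + band_h), :] += 160.0

    # subchondral sclerosis: brightening strip on the tibial (lower) margin
    scl_h = max(1, int(s * 0.04))
    img[bot_lo : min(s, bot_lo + scl_h), :] += 30.0 * grade / 4.0

    # osteophytes: bright blobs at the joint margins, count grows with grade
    yy, xx = np.mgrid[0:s, 0:s]
    for _ in range(2 * grade):
        bx = rng.uniform(0.05 * s, 0.2 * s)
        if rng.random() < 0.5:
            bx = s - bx
        by = center + rng.choice([-1.0, 1.0]) * gap / 2
        r = max(1.5, 0.02 * s)
        img += 90.0 * np.exp(-(((xx - bx) ** 2 + (yy - by) ** 2) / (2 * r**2)))

    if spec.domain_shift == "external":
        img = img * EXTERNAL_CONTRAST_SCALE + EXTERNAL_BRIGHTNESS_OFFSET

    if rng.random() < spec.effective_letterbox_prob:
        bar = max(2, int(round(s * rng.uniform(0.04, 0.1))))
        fill = 0.0 if rng.random() < 0.5 else 255.0
        img[:bar, :] = fill
        img[-bar:, :] = fill

    return np.clip(img, 0.0, 255.0)


def measure_gap(image: np.ndarray, threshold: float = 100.0) -> int:
    """Width (rows) of the longest dark run between the two bright bands.

    Measurement helper for tests: scans the central column band for
    consecutive rows whose mean intensity is below ``threshold``.
    """
    s = image.shape[1]
    profile = image[:, s // 4 : 3 * s // 4].mean(axis=1)
    dark = profile < threshold
    bright = np.flatnonzero(~dark)
    if len(bright) == 0:
        return int(dark.sum())
    lo, hi = bright[0], bright[-1]
    runs, cur = [], 0
    for d in dark[lo : hi + 1]:
        cur = cur + 1 if d else 0
        runs.append(cur)
    return max(runs) if runs else 0


def _record_rng(spec: SyntheticSpec, image_name: str) -> np.random.Generator:
    # per-record stream keyed by (seed, image name): rendering order never
    # changes pixel content, and single images can be re-rendered in isolation
    digest = hashlib.sha256(f"{spec.seed}:{image_name}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "big"))


def render_cohort(manifest: CohortManifest, spec: SyntheticSpec):
    """Yield (record, pixels) for every manifest row, deterministically."""
    for rec in manifest.frame.itertuples(index=False):
        rng = _record_rng(spec, rec.image)
        yield rec, render_image(rec.kl_grade, spec, rng)


def write_cohort(manifest: CohortManifest, spec: SyntheticSpec, out_dir) -> Path:
    """Render every record to an 8-bit grayscale PNG plus a manifest CSV.

    Returns the manifest path.  Image paths in the CSV are relative to
    ``out_dir`` so the tree relocates cleanly.
    """
    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rel_paths = []
    for rec, pixels in render_cohort(manifest, spec):
        rel = Path("images") / rec.image
        try:
            Image.fromarray(np.round(pixels).astype(np.uint8), mode="L").save(out / rel)
        except OSError as exc:  # pragma: no cover - I/O failure path
            raise OSError(f"failed writing {out / rel}: {exc}") from exc
        rel_paths.append(str(rel))
    frame = manifest.frame.assign(image=rel_paths)
    csv_path = out / "manifest.csv"
    frame.to_csv(csv_path, index=False, columns=MANIFEST_COLUMNS)
    return csv_path


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF as a 2-D float intensity array in [0, 255]."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.float64)


def generate_cohort(spec: SyntheticSpec, out_dir) -> CohortManifest:
    """Roster + rendered images + CSV in one call; returns the re-read manifest."""
    roster = generate_roster(spec)
    csv_path = write_cohort(roster, spec, out_dir)
    return CohortManifest.from_csv(csv_path)
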