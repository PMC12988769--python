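"""Cohort manifests, patient-ID parsing, and leakage-free patient-wise splitting.

Radiograph cohorts with bilateral knees are correlated at the participant
level: the left and right knee of one patient share anatomy and acquisition.
Splitting at the image level therefore leaks patient-specific cues across
partitions and inflates agreement statistics.  This module partitions at the
patient level, stratified by each patient's maximum KL grade, so that every
image of a patient lands in the same partition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MANIFEST_COLUMNS = ["image", "patient_id", "laterality", "kl_grade", "cohort"]
PARTITIONS = ("train", "val", "test")


class LeakageError(RuntimeError):
    """Raised when images of one patient straddle partitions."""


def parse_patient_id(image_stem: str) -> tuple[str, str]:
    """Split a composite image stem into (patient_id, laterality).

    Stems ending in ``L`` or ``R`` follow the bilateral naming convention
    ``{patient_id}{L|R}`` (e.g. ``9001400L``); anything else is a
    single-image patient with laterality ``none``.
    """
    if not image_stem:
        raise ValueError("empty image stem")
    if image_stem[-1] in ("L", "R") and len(image_stem) > 1:
        return image_stem[:-1], image_stem[-1]
    return image_stem, "none"


@dataclass
class CohortManifest:
    """Table of image records: one row per radiograph.

    Columns: image (path), patient_id, laterality (L/R/none), kl_grade (0-4),
    cohort (free-form tag, e.g. ``internal``/``external``).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        f = self.frame
        grades = f["kl_grade"].to_numpy()
        if len(f) and (not np.issubdtype(grades.dtype, np.integer)):
            f = f.assign(kl_grade=f["kl_grade"].astype(int))
            grades = f["kl_grade"].to_numpy()
            self.frame = f
        if len(f) and ((grades < 0).any() or (grades > 4).any()):
            raise ValueError("kl_grade outside 0..4")
        if f["image"].duplicated().any():
            dup = f.loc[f["image"].duplicated(), "image"].iloc[0]
            raise ValueError(f"duplicate image path: {dup}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def patient_ids(self) -> np.ndarray:
        return self.frame["patient_id"].unique()

    @classmethod
    def from_csv(cls, path) -> "CohortManifest":
        frame = pd.read_csv(path, dtype={"patient_id": str})
        return cls(frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, columns=MANIFEST_COLUMNS)


def patient_strata(manifest: CohortManifest) -> dict[str, int]:
    """Per-patient stratum: the maximum KL grade over that patient's images."""
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    return (
        manifest.frame.groupby("patient_id")["kl_grade"].max().astype(int).to_dict()
    )


@dataclass
class SplitAssignment:
    """Patient-level partition map with its provenance (fractions, seed)."""

    partition: dict[str, str]
    strata: dict[str, int]
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 42

    def patients(self, part: str) -> list[str]:
        return [p for p, q in self.partition.items() if q == part]

    def image_partition(self, manifest: CohortManifest) -> pd.Series:
        return manifest.frame["patient_id"].map(self.partition)

    def subset(self, manifest: CohortManifest, part: str) -> CohortManifest:
        mask = self.image_partition(manifest) == part
        return CohortManifest(manifest.frame.loc[mask].reset_index(drop=True))

    def to_csv(self, path) -> None:
        rows = [
            {"patient_id": p, "stratum": self.strata.get(p, -1), "partition": q}
            for p, q in sorted(self.partition.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fractions=(0.70, 0.15, 0.15), seed=42) -> "SplitAssignment":
        frame = pd.read_csv(path, dtype={"patient_id": str})
        return cls(
            partition=dict(zip(frame["patient_id"], frame["partition"])),
            strata=dict(zip(frame["patient_id"], frame["stratum"].astype(int))),
            fractions=tuple(fractions),
            seed=seed,
        )


def _largest_remainder(sizes: np.ndarray, total: int) -> np.ndarray:
    """Apportion `total` over groups proportionally to `sizes` (Hare quota).

    Floors the quotas, then hands the remaining units to the largest
    fractional parts (ties broken by group index).  Never allocates more
    than a group's size.
    """
    sizes = np.asarray(sizes, dtype=float)
    n = sizes.sum()
    if n == 0:
        return np.zeros(len(sizes), dtype=int)
    quota = sizes * (total / n)
    alloc = np.floor(quota).astype(int)
    rem = total - alloc.sum()
    order = np.argsort(-(quota - alloc), kind="stable")
    for g in order[:rem]:
        alloc[g] += 1
    return np.minimum(alloc, sizes.astype(int))


def patient_wise_split(
    manifest: CohortManifest,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 42,
) -> SplitAssignment:
    """Stratified 70/15/15 split on patients; all images follow their patient.

    Two-stage allocation: stage 1 holds out ``ceil((f_val+f_test)*N)``
    patients (train keeps the rest); stage 2 splits the holdout into
    val = floor(half) and test = ceil(half).  Within each stage, per-stratum
    counts come from largest-remainder apportionment against the fixed global
    partition sizes, and patients are drawn by a seeded shuffle within their
    stratum.  Deterministic under (manifest, fractions, seed).
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")

    strata = patient_strata(manifest)
    patients = sorted(strata)
    n = len(patients)
    f_train, f_val, f_test = fractions
    # round before ceil: binary float puts 0.15+0.15 a hair above 0.30, which
    # would otherwise bump an exact-integer quota to the next integer
    n_hold = math.ceil(round((f_val + f_test) * n, 9))
    n_test = math.ceil(round(n_hold * f_test / (f_val + f_test), 9))
    n_val = n_hold - n_test

    levels = sorted(set(strata.values()))
    by_stratum = {g: [p for p in patients if strata[p] == g] for g in levels}
    sizes = np.array([len(by_stratum[g]) for g in levels])
    if any(sizes < 3):
        warnings.warn(
            "stratum with fewer patients than partitions; best-effort allocation",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    hold_alloc = _largest_remainder(sizes, n_hold)
    partition: dict[str, str] = {}
    holdout_by_stratum: dict[int, list[str]] = {}
    for g, k in zip(levels, hold_alloc):
        pool = list(by_stratum[g])
        rng.shuffle(pool)
        holdout_by_stratum[g] = pool[:k]
        for p in pool[k:]:
            partition[p] = "train"

    hold_sizes = np.array([len(holdout_by_stratum[g]) for g in levels])
    test_alloc = _largest_remainder(hold_sizes, n_test)
    for g, k in zip(levels, test_alloc):
        pool = holdout_by_stratum[g]
        for p in pool[:k]:
            partition[p] = "test"
        for p in pool[k:]:
            partition[p] = "val"

    # Apportionment bounded by stratum sizes can undershoot the global
    # targets in pathological cases; top up from the largest remaining pools.
    counts = {q: sum(1 for v in partition.values() if v == q) for q in PARTITIONS}
    assert counts["train"] + counts["val"] + counts["test"] == n
    if counts["val"] != n_val or counts["test"] != n_test:
        warnings.warn("best-effort allocation deviates from target sizes", stacklevel=2)

    assignment = SplitAssignment(partition, strata, fractions, seed)
    assert_no_leakage(assignment, manifest)
    return assignment


def assert_no_leakage(assignment: SplitAssignment, manifest: CohortManifest) -> dict:
    """Verify zero patient overlap across partitions; raise naming offenders.

    Returns a small report dict (patient/image counts per partition) when the
    check passes.  An empty manifest passes vacuously.
    """
    if len(manifest) == 0:
        return {p: {"patients": 0, "images": 0} for p in PARTITIONS}
    frame = manifest.frame
    unassigned = sorted(set(frame["patient_id"]) - set(assignment.partition))
    if unassigned:
        raise LeakageError(f"patients missing from assignment: {unassigned[:10]}")
    # the patient-level map is single-valued by construction; the real check is
    # that an externally supplied image-level table never contradicts it
    if "partition" in frame.columns:
        img_parts = frame.groupby("patient_id")["partition"].nunique()
        bad = sorted(img_parts[img_parts > 1].index)
        if bad:
            raise LeakageError(f"bilateral pair split across partitions: {bad[:10]}")
        disagrees = sorted(
            pid
            for pid, part in frame.groupby("patient_id")["partition"].first().items()
            if assignment.partition[pid] != part
        )
        if disagrees:
            raise LeakageError(
                f"image partition contradicts patient assignment: {disagrees[:10]}"
            )
    parts = frame["patient_id"].map(assignment.partition)
    report = {}
    for q in PARTITIONS:
        mask = parts == q
        report[q] = {
            "patients": int(frame.loc[mask, "patient_id"].nunique()),
            "images": int(mask.sum()),
        }
    seen: dict[str, str] = {}
    for pid, q in zip(frame["patient_id"], parts):
        if pid in seen and seen[pid] != q:  # pragma: no cover - defensive
            raise LeakageError(f"patient {pid} appears in {seen[pid]} and {q}")
        seen[pid] = q
    return report
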