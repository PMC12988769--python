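"""Ordinal decoding, validation-only cutpoint tuning, and TTA aggregation.

The ordinal head emits four independent cumulative probabilities
``P(grade > k-1)``.  A grade is decoded as the *count of exceedances* over
four nondecreasing cutpoints — well-defined even when the independent
sigmoids are non-monotone across thresholds.  Cutpoints live in
[0.30, 0.70] and are tuned by coordinate descent to maximize
quadratic-weighted kappa on the validation split only; they are then
applied unchanged to held-out data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .metrics import qwk
from .model import HeadOutputs
from .nn import sigmoid, softmax

CUTPOINT_LO = 0.30
CUTPOINT_HI = 0.70
DEFAULT_CUTPOINTS = (0.5, 0.5, 0.5, 0.5)


@dataclass(frozen=True)
class Cutpoints:
    """Four nondecreasing decision thresholds on cumulative probabilities."""

    values: tuple[float, float, float, float] = DEFAULT_CUTPOINTS

    def __post_init__(self) -> None:
        v = tuple(float(x) for x in self.values)
        if len(v) != 4:
            raise ValueError("exactly 4 cutpoints required")
        if any(x < CUTPOINT_LO - 1e-12 or x > CUTPOINT_HI + 1e-12 for x in v):
            raise ValueError(f"cutpoints must lie in [{CUTPOINT_LO}, {CUTPOINT_HI}]")
        if any(v[i] > v[i + 1] + 1e-12 for i in range(3)):
            raise ValueError("cutpoints must be nondecreasing")
        object.__setattr__(self, "values", v)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=np.float64)


def decode(cumulative_probs: np.ndarray, cutpoints: Cutpoints) -> np.ndarray:
    """Grade = number of thresholds whose cumulative probability exceeds its
    cutpoint (strict inequality; a tie does not count).

    Accepts a (4,) vector or (N, 4) matrix; returns int grades in 0..4.
    Monotone: raising any cumulative probability never lowers the grade.
    """
    p = np.asarray(cumulative_probs, dtype=np.float64)
    if p.shape[-1] != 4:
        raise ValueError("expected 4 cumulative probabilities per sample")
    if (p < -1e-9).any() or (p > 1 + 1e-9).any():
        raise ValueError("cumulative probabilities must lie in [0, 1]")
    c = cutpoints.as_array()
    grades = (p > c).sum(axis=-1)
    return grades.astype(int)


def p_kl_ge2(class_probs: np.ndarray) -> np.ndarray:
    """Probability of clinically significant disease: p2 + p3 + p4."""
    p = np.asarray(class_probs, dtype=np.float64)
    if p.shape[-1] != 5:
        raise ValueError("expected 5 class probabilities")
    sums = p.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("class probabilities must sum to 1")
    return p[..., 2:].sum(axis=-1)


@dataclass
class Prediction:
    """Aggregated per-image prediction."""

    grade: int
    cumulative_probs: np.ndarray  # (4,)
    class_probs: np.ndarray  # (5,)
    p_ge2: float
    binary_head_prob: float | None = None


def tta_aggregate(
    views: list[HeadOutputs],
    cutpoints: Cutpoints = Cutpoints(),
    average: str = "probability",
) -> Prediction:
    """Average per-view predictions and decode the grade.

    ``average="probability"`` (default) converts each view's logits to
    probabilities (sigmoid/softmax) and takes the arithmetic mean, keeping
    class probabilities on the simplex; ``average="logit"`` averages raw
    logits first.  Decode runs on the averaged cumulative probabilities and
    the KL>=2 probability on the averaged class probabilities.
    """
    if not views:
        raise ValueError("need at least one view to aggregate")
    if average not in ("probability", "logit"):
        raise ValueError("average must be 'probability' or 'logit'")
    ords = np.stack([v.ordinal_logits.reshape(4) for v in views])
    lds = np.stack([v.ld_logits.reshape(-1) for v in views])
    bins = (
        np.array([float(np.ravel(v.binary_logit)[0]) for v in views])
        if views[0].binary_logit is not None
        else None
    )
    if average == "probability":
        cum = sigmoid(ords).mean(axis=0)
        cls = softmax(lds, axis=1).mean(axis=0)
        pbin = float(sigmoid(bins).mean()) if bins is not None else None
    else:
        cum = sigmoid(ords.mean(axis=0))
        cls = softmax(lds.mean(axis=0))
        pbin = float(sigmoid(np.array([bins.mean()]))[0]) if bins is not None else None
    grade = int(decode(cum, cutpoints))
    return Prediction(
        grade=grade,
        cumulative_probs=cum,
        class_probs=cls,
        p_ge2=float(p_kl_ge2(cls)),
        binary_head_prob=pbin,
    )


def tune_cutpoints(
    cumulative_probs: np.ndarray,
    true_grades: np.ndarray,
    grid_step: float = 0.01,
    partition: str = "val",
) -> tuple[Cutpoints, float]:
    """Coordinate descent over a nondecreasing cutpoint grid, maximizing QWK.

    Starts at (0.5, 0.5, 0.5, 0.5); sweeps thresholds k = 1..4 repeatedly
    over a ``grid_step``-resolution grid on [0.30, 0.70] restricted to values
    that keep the vector nondecreasing; accepts a move only on *strict* QWK
    improvement (ties keep the lowest cutpoint); stops when a full sweep
    changes nothing.  Returns ``(cutpoints, qwk_on_tuning_data)``; the result
    is never worse than the 0.5 start.

    Tuning is legal on validation data only — ``partition="test"`` is
    refused outright (leakage guard).
    """
    if partition == "test":
        raise ValueError(
            "cutpoint tuning on test-labeled data is leakage; tune on validation"
        )
    p = np.asarray(cumulative_probs, dtype=np.float64)
    y = np.asarray(true_grades, dtype=int)
    if p.ndim != 2 or p.shape[1] != 4 or len(p) != len(y) or len(y) == 0:
        raise ValueError("need a nonempty (N, 4) probability matrix with N grades")
    if len(np.unique(y)) < 2:
        warnings.warn("single-class validation set; returning default cutpoints",
                      stacklevel=2)
        c = Cutpoints()
        return c, qwk(y, decode(p, c))

    n_steps = int(round((CUTPOINT_HI - CUTPOINT_LO) / grid_step))
    grid = CUTPOINT_LO + grid_step * np.arange(n_steps + 1)
    cuts = np.full(4, 0.5)
    best = qwk(y, decode(p, Cutpoints(tuple(cuts))))
    changed = True
    while changed:
        changed = False
        for k in range(4):
            for c in grid:  # ascending: ties keep the lowest cutpoint
                if abs(c - cuts[k]) < 1e-12:
                    continue
                trial = cuts.copy()
                trial[k] = c
                # project neighbors so the vector stays nondecreasing
                trial[:k] = np.minimum(trial[:k], c)
                trial[k + 1 :] = np.maximum(trial[k + 1 :], c)
                score = qwk(y, decode(p, Cutpoints(tuple(trial))))
                if score > best + 1e-12:
                    best = score
                    cuts = trial
                    changed = True
    return Cutpoints(tuple(cuts)), float(best)


def brute_force_cutpoints(
    cumulative_probs: np.ndarray, true_grades: np.ndarray, grid_step: float = 0.1
) -> tuple[Cutpoints, float]:
    """Exhaustive search over all nondecreasing cutpoint grids.

    Exponential in grid size — an independent oracle for testing the
    coordinate-descent tuner on coarse grids, not a production path.
    """
    p = np.asarray(cumulative_probs, dtype=np.float64)
    y = np.asarray(true_grades, dtype=int)
    n_steps = int(round((CUTPOINT_HI - CUTPOINT_LO) / grid_step))
    grid = CUTPOINT_LO + grid_step * np.arange(n_steps + 1)
    best_score, best_cuts = -np.inf, None
    m = len(grid)
    for i in range(m):
        for j in range(i, m):
            for k in range(j, m):
                for l in range(k, m):
                    cand = Cutpoints((grid[i], grid[j], grid[k], grid[l]))
                    score = qwk(y, decode(p, cand))
                    if score > best_score:
                        best_score, best_cuts = score, cand
    return best_cuts, float(best_score)
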