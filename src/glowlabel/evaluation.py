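"""Detector scoring (pixel error, on-target PR/AUC) and test-time scale search.

An on-target prediction must satisfy three conditions: its ground-truth
label is present, its confidence is at or above the threshold, and its pixel
error is below a fraction of the image width.  Precision and recall are
traced over all confidence thresholds.  Scale optimization runs a two-level
hierarchical grid search over image pre-scaling factors, maximizing mean
prediction confidence per frame or per clip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import DetectorFailure, InputError
from .serial import LandmarkLabel


@dataclass(frozen=True)
class Prediction:
    """Detector output for one frame, in original-image coordinates."""

    frame_index: int
    x: float
    y: float
    confidence: float

    def __post_init__(self):
        if not math.isfinite(self.confidence):
            raise ValueError("confidence must be finite")


@dataclass
class PRCurve:
    """Precision/recall pairs over all confidence thresholds, plus AUC."""

    points: list[tuple[float, float]]  # (recall, precision)
    auc: float
    error_threshold_frac: float = 0.05


@dataclass(frozen=True)
class ScaleGrid:
    """Two-level hierarchical scale grid: ``base**k`` then ``base**(k*+j)``.

    The printed fine-offset upper bound 0.33 is unreachable with step 0.16
    from -0.33; the grid uses exactly five fine steps.
    """

    coarse_exponents: tuple[float, ...] = (-1.0, -0.5, 0.0, 0.5, 1.0)
    fine_offsets: tuple[float, ...] = (-0.33, -0.17, -0.01, 0.15, 0.31)
    base: float = 2.0

    def __post_init__(self):
        if not self.coarse_exponents or not self.fine_offsets:
            raise ValueError("grid levels must be nonempty")
        if list(self.coarse_exponents) != sorted(self.coarse_exponents):
            raise ValueError("coarse exponents must be sorted")
        if list(self.fine_offsets) != sorted(self.fine_offsets):
            raise ValueError("fine offsets must be sorted")

    def full_exponents(self) -> list[float]:
        """Every exponent the two-level search can ever evaluate."""
        out = []
        for k in self.coarse_exponents:
            for j in self.fine_offsets:
                out.append(k + j)
        return sorted(set(out) | set(self.coarse_exponents))


def pixel_error(pred: Prediction, truth: LandmarkLabel) -> float | None:
    """Euclidean distance to ground truth; None when the truth is absent."""
    if pred.frame_index != truth.frame_index:
        raise InputError(
            f"frame mismatch: prediction {pred.frame_index}, truth {truth.frame_index}"
        )
    if not truth.present:
        return None
    return float(math.hypot(pred.x - truth.x, pred.y - truth.y))


def pr_curve(
    preds: Sequence[Prediction],
    truths: Sequence[LandmarkLabel],
    image_width: float,
    error_threshold_frac: float = 0.05,
) -> PRCurve:
    """Precision-recall over the sorted distinct confidence thresholds.

    On-target at threshold t: truth present AND confidence >= t AND
    pixel error < ``error_threshold_frac * image_width``.  Recall divides by
    the number of present truths, precision by the number of predictions at
    or above the threshold.  AUC is the trapezoidal integral over recall
    with a (recall=0, first-precision) anchor.
    """
    if len(preds) != len(truths):
        raise InputError("predictions and truths must align one-to-one")
    truth_by_frame = {t.frame_index: t for t in truths}
    if len(truth_by_frame) != len(truths):
        raise InputError("duplicate truth frame indices")
    n_present = sum(t.present for t in truths)
    if n_present == 0:
        raise InputError("recall undefined: no present ground-truth labels")

    err_cut = error_threshold_frac * image_width
    conf = np.array([p.confidence for p in preds])
    good = np.zeros(len(preds), dtype=bool)  # present truth and small error
    for i, p in enumerate(preds):
        t = truth_by_frame.get(p.frame_index)
        if t is None:
            raise InputError(f"no truth for frame {p.frame_index}")
        e = pixel_error(p, t)
        good[i] = e is not None and e < err_cut

    points: list[tuple[float, float]] = []
    for thr in sorted(set(conf.tolist())):
        selected = conf >= thr
        n_sel = int(selected.sum())
        on_target = int((selected & good).sum())
        precision = on_target / n_sel if n_sel else 1.0
        recall = on_target / n_present
        points.append((recall, precision))

    pts = sorted(points)
    recalls = [0.0] + [r for r, _ in pts]
    precisions = [pts[0][1]] + [p for _, p in pts]
    auc = float(np.trapezoid(precisions, recalls))
    return PRCurve(points=points, auc=auc, error_threshold_frac=error_threshold_frac)


# ---------------------------------------------------------------------------
# scale optimization

Detector = Callable[[object, float], Prediction]


@dataclass
class ScaleOptResult:
    level: str
    scales: list[float]  # one entry for clip level, one per frame otherwise
    predictions: list[Prediction | None]  # None where the detector failed
    objective: dict[float, float] = field(default_factory=dict)


def _detect_all(
    detector: Detector, frames: Sequence, scale: float
) -> tuple[list[Prediction | None], float | None]:
    """Run the detector at one scale; mean confidence over non-failed frames."""
    preds: list[Prediction | None] = []
    confs = []
    for frame in frames:
        try:
            p = detector(frame, scale)
        except DetectorFailure:
            p = None
        preds.append(p)
        if p is not None:
            confs.append(p.confidence)
    return preds, (float(np.mean(confs)) if confs else None)


def _two_level_argmax(
    evaluate: Callable[[float], float | None], grid: ScaleGrid
) -> tuple[float, dict[float, float]]:
    objective: dict[float, float] = {}

    def score(exponent: float) -> float:
        scale = grid.base**exponent
        if scale not in objective:
            val = evaluate(scale)
            objective[scale] = -math.inf if val is None else val
        return objective[scale]

    best_k = grid.coarse_exponents[0]
    best = score(best_k)
    for k in grid.coarse_exponents[1:]:
        v = score(k)
        if v > best:
            best_k, best = k, v
    best_e = best_k
    for j in grid.fine_offsets:
        v = score(best_k + j)
        if v > best:
            best_e, best = best_k + j, v
    if best == -math.inf:
        raise DetectorFailure("detector failed at every scale")
    return grid.base**best_e, objective


def scale_optimize(
    detector: Detector,
    frames: Sequence,
    level: str = "clip",
    grid: ScaleGrid = ScaleGrid(),
) -> ScaleOptResult:
    """Two-level grid search over pre-scaling factors maximizing confidence.

    ``level="clip"`` picks a single scale for the whole clip (objective:
    clip-mean confidence); ``level="frame"`` repeats the search per frame.
    The coarse level sweeps ``base**k`` over the coarse exponents; the fine
    level sweeps ``base**(k* + j)`` around the coarse winner.  Ties keep the
    first (smallest) grid point.  Frames where the detector raises
    :class:`DetectorFailure` are skipped from the objective.
    """
    if level not in ("clip", "frame"):
        raise InputError(f"unknown level {level!r}")
    frames = list(frames)
    if not frames:
        raise InputError("need at least one frame")

    if level == "clip":
        cache: dict[float, list[Prediction | None]] = {}

        def evaluate(scale: float) -> float | None:
            preds, mean_conf = _detect_all(detector, frames, scale)
            cache[scale] = preds
            return mean_conf

        chosen, objective = _two_level_argmax(evaluate, grid)
        return ScaleOptResult(
            level="clip",
            scales=[chosen],
            predictions=cache[chosen],
            objective=objective,
        )

    scales: list[float] = []
    predictions: list[Prediction | None] = []
    n_failed = 0
    for frame in frames:
        try:

            def evaluate(scale: float, _frame=frame) -> float | None:
                _, mean_conf = _detect_all(detector, [_frame], scale)
                return mean_conf

            chosen, _ = _two_level_argmax(evaluate, grid)
            pred, _ = _detect_all(detector, [frame], chosen)
            scales.append(chosen)
            predictions.append(pred[0])
        except DetectorFailure:
            scales.append(float("nan"))
            predictions.append(None)
            n_failed += 1
    if n_failed == len(frames):
        raise DetectorFailure("detector failed on every frame")
    return ScaleOptResult(level="frame", scales=scales, predictions=predictions)


def confidence_trace(
    preds: Sequence[Prediction], window: int = 100
) -> list[tuple[float, float, float]]:
    """(x, y, confidence) of the most recent ``window`` predictions."""
    if window < 1:
        raise InputError("window must be >= 1")
    recent = list(preds)[-window:]
    return [(p.x, p.y, p.confidence) for p in recent]


def mean_displacement(preds: Sequence[Prediction]) -> float:
    """Average landmark displacement between adjacent frames.

    Smoothness proxy objective; implemented but not used by default, as it
    can rate spurious-but-smooth trajectories highly.
    """
    if len(preds) < 2:
        return 0.0
    xy = np.array([(p.x, p.y) for p in preds])
    return float(np.mean(np.hypot(*np.diff(xy, axis=0).T)))


# ---------------------------------------------------------------------------
# I/O and reports


def predictions_to_frame(preds: Sequence[Prediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.frame_index, p.x, p.y, p.confidence) for p in preds],
        columns=["frame_index", "x", "y", "confidence"],
    )


def frame_to_predictions(df: pd.DataFrame) -> list[Prediction]:
    return [
        Prediction(int(r.frame_index), float(r.x), float(r.y), float(r.confidence))
        for r in df.itertuples(index=False)
    ]


def evaluation_report(
    preds: Sequence[Prediction],
    truths: Sequence[LandmarkLabel],
    image_width: float,
    error_threshold_frac: float = 0.05,
) -> dict:
    """AUC plus pixel-error quartiles over frames with present truth."""
    curve = pr_curve(preds, truths, image_width, error_threshold_frac)
    truth_by_frame = {t.frame_index: t for t in truths}
    errors = [
        e
        for p in preds
        if (e := pixel_error(p, truth_by_frame[p.frame_index])) is not None
    ]
    q25, q50, q75 = (
        np.percentile(errors, [25, 50, 75]) if errors else (math.nan,) * 3
    )
    return {
        "auc": curve.auc,
        "n_predictions": len(preds),
        "n_present_truths": int(sum(t.present for t in truths)),
        "pixel_error_median": float(q50),
        "pixel_error_q25": float(q25),
        "pixel_error_q75": float(q75),
    }
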