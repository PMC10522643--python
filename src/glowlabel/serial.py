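"""Serial labeling: dye mask extraction, cleaning, centroids, interpolation.

One landmark is coated in dye; each UV frame shows (nearly) only the
fluorescing dye blob.  Thresholding, morphological cleaning, and a centroid
turn each UV frame into a label for the visible frame that follows it.
Frames with no surviving mask yield an *absent* label, which is kept in the
track as a negative example.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import CubicSpline
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, opening

from .acquisition import TriggerSchedule, UVVisiblePair
from .errors import InputError

SOURCE_CENTROID = "centroid"
SOURCE_INTERPOLATED = "interpolated"
SOURCE_DETECTOR = "detector"
SOURCE_PROPAGATED = "propagated"

_SOURCES = (SOURCE_CENTROID, SOURCE_INTERPOLATED, SOURCE_DETECTOR, SOURCE_PROPAGATED)


@dataclass(frozen=True)
class DyeMaskConfig:
    """Thresholding and cleaning parameters for dye-mask extraction.

    ``threshold`` is either an absolute cutoff in [0, 1] or the string
    ``"otsu"``; ``threshold_floor`` is a lower bound on the resolved Otsu
    value, guarding against signal-free frames where Otsu splits the noise.
    """

    threshold: float | str = "otsu"
    threshold_floor: float = 0.1
    open_radius_px: int = 1
    close_radius_px: int = 2
    min_area_px: int = 20
    max_components: int = 1

    def __post_init__(self):
        if self.open_radius_px < 0 or self.close_radius_px < 0:
            raise ValueError("morphology radii must be >= 0")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if self.max_components < 1:
            raise ValueError("max_components must be >= 1")
        if not isinstance(self.threshold, str) and not 0 <= self.threshold <= 1:
            raise ValueError("fixed threshold must lie in [0, 1]")


@dataclass(frozen=True)
class LandmarkLabel:
    """(x, y, present) for one landmark in one frame.

    Coordinates are continuous, 0-based, pixel-center, origin top-left,
    x rightward and y downward.  Absent labels carry NaN coordinates.
    """

    frame_index: int
    x: float
    y: float
    present: bool
    source: str = SOURCE_CENTROID

    def __post_init__(self):
        if self.source not in _SOURCES:
            raise ValueError(f"unknown label source {self.source!r}")

    @classmethod
    def absent(cls, frame_index: int, source: str = SOURCE_CENTROID) -> "LandmarkLabel":
        return cls(frame_index, float("nan"), float("nan"), False, source)

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class LabelTrack:
    """Ordered labels for one landmark from one camera."""

    labels: list[LandmarkLabel]
    width: int
    height: int

    def __post_init__(self):
        idx = [l.frame_index for l in self.labels]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def present_mask(self) -> np.ndarray:
        return np.array([l.present for l in self.labels], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (l.frame_index, l.x, l.y, l.present, l.source)
                for l in self.labels
            ],
            columns=["frame_index", "x", "y", "present", "source"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, width: int, height: int) -> "LabelTrack":
        labels = [
            LandmarkLabel(
                int(r.frame_index),
                float(r.x),
                float(r.y),
                bool(r.present),
                str(r.source),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(labels, width, height)


def write_track(track: LabelTrack, path) -> None:
    track.to_frame().to_csv(path, index=False)


def read_track(path, width: int, height: int) -> LabelTrack:
    return LabelTrack.from_frame(pd.read_csv(path), width, height)


# ---------------------------------------------------------------------------
# mask extraction


def extract_dye_mask(uv_image: np.ndarray, cfg: DyeMaskConfig) -> np.ndarray:
    """Threshold a normalized single-channel UV image into a binary mask.

    Pixels with intensity >= the resolved threshold are marked.  Cleaning is
    deliberately a separate stage.
    """
    img = np.asarray(uv_image, dtype=float)
    if img.ndim != 2:
        raise InputError("UV image must be single-channel; reduce color first")
    if not np.all(np.isfinite(img)):
        raise InputError("UV image contains non-finite pixels")

    if isinstance(cfg.threshold, str):
        if cfg.threshold != "otsu":
            raise InputError(f"unknown threshold method {cfg.threshold!r}")
        if img.max() <= img.min():
            return np.zeros(img.shape, dtype=bool)
        thr = max(float(threshold_otsu(img)), cfg.threshold_floor)
    else:
        thr = float(cfg.threshold)
    return img >= thr


def reduce_channel(image: np.ndarray, channel: int = 0) -> np.ndarray:
    """Pick the dye-emission channel from a color UV frame."""
    img = np.asarray(image)
    if img.ndim == 2:
        return img
    if img.ndim == 3:
        return img[..., channel]
    raise InputError("expected a 2-D or 3-D image")


def clean_mask(mask: np.ndarray, cfg: DyeMaskConfig) -> np.ndarray:
    """Morphologically clean a binary mask.

    Opening then closing with the configured radii, removal of components
    below ``min_area_px``, then retention of at most ``max_components``
    largest components.  Idempotent.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return m.copy()
    if cfg.open_radius_px > 0:
        m = opening(m, disk(cfg.open_radius_px))
    if cfg.close_radius_px > 0:
        m = closing(m, disk(cfg.close_radius_px))
    labeled, n = ndimage.label(m)
    if n == 0:
        return np.zeros_like(m)
    areas = ndimage.sum_labels(np.ones_like(m, dtype=int), labeled, np.arange(1, n + 1))
    keep = np.flatnonzero(areas >= cfg.min_area_px) + 1
    if keep.size > cfg.max_components:
        order = np.argsort(areas[keep - 1])[::-1]
        keep = keep[order[: cfg.max_components]]
    return np.isin(labeled, keep)


def mask_centroid(mask: np.ndarray, frame_index: int = 0) -> LandmarkLabel:
    """Unweighted centroid of the mask pixels, absent when the mask is empty."""
    m = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(m)
    if xs.size == 0:
        return LandmarkLabel.absent(frame_index)
    return LandmarkLabel(frame_index, float(xs.mean()), float(ys.mean()), True)


def label_sequence(
    pairs: Sequence[UVVisiblePair],
    cfg: DyeMaskConfig,
    loader: Callable[[str], np.ndarray] | None = None,
    images: Sequence[np.ndarray] | None = None,
) -> tuple[LabelTrack, list[tuple[int, str]]]:
    """Extract one label per UV/visible pair.

    UV images are supplied either via ``images`` (aligned with ``pairs``) or
    loaded from ``pair.uv.path`` with ``loader``.  Labels attach to the
    visible frame index.  Per-frame read failures are recorded and processing
    continues with an absent label.
    """
    if images is None and loader is None:
        raise InputError("supply either pre-loaded images or a loader")
    labels: list[LandmarkLabel] = []
    failures: list[tuple[int, str]] = []
    shape = None
    for i, pair in enumerate(pairs):
        frame_index = pair.visible.index
        try:
            img = images[i] if images is not None else loader(pair.uv.path)
            img = reduce_channel(img)
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise InputError(f"frame size {img.shape} != {shape}")
            mask = clean_mask(extract_dye_mask(img, cfg), cfg)
            labels.append(mask_centroid(mask, frame_index))
        except InputError as exc:
            failures.append((frame_index, str(exc)))
            labels.append(LandmarkLabel.absent(frame_index))
    if shape is None:
        shape = (0, 0)
    track = LabelTrack(labels, width=shape[1], height=shape[0])
    return track, failures


# ---------------------------------------------------------------------------
# temporal interpolation


def interpolate_track(
    track: LabelTrack,
    method: str,
    schedule: TriggerSchedule,
    max_absent_span: int = 2,
) -> LabelTrack:
    """Re-estimate each label at the visible shutter instant.

    UV centroids are samples at the UV shutter time of their cycle; the label
    they stand in for belongs to the visible shutter time, one shutter offset
    later.  Linear or cubic-in-time interpolation of the present samples
    shifts each label to its proper instant.  Runs of absent labels longer
    than ``max_absent_span`` frames stay absent; shorter runs are filled.
    """
    if method not in ("linear", "cubic"):
        raise InputError(f"unknown interpolation method {method!r}")
    present = [l for l in track.labels if l.present]
    needed = 2 if method == "linear" else 4
    if len(present) < needed:
        warnings.warn(
            f"{method} interpolation needs >= {needed} present labels; "
            "returning track unchanged",
            stacklevel=2,
        )
        return track

    cyc = schedule.cycle_ms
    uv_t = np.array(
        [l.frame_index * cyc + schedule.uv_shutter_ms for l in present]
    )
    xs = np.array([l.x for l in present])
    ys = np.array([l.y for l in present])
    if method == "linear":
        fx = lambda t: np.interp(t, uv_t, xs)  # noqa: E731
        fy = lambda t: np.interp(t, uv_t, ys)  # noqa: E731
    else:
        fx = CubicSpline(uv_t, xs)
        fy = CubicSpline(uv_t, ys)

    # absent-run bookkeeping: frames in runs longer than the span stay absent
    run_len: dict[int, int] = {}
    run: list[int] = []
    for l in track.labels:
        if not l.present:
            run.append(l.frame_index)
        else:
            for fi in run:
                run_len[fi] = len(run)
            run = []
    for fi in run:
        run_len[fi] = len(run)

    t_lo, t_hi = uv_t[0], uv_t[-1]
    out: list[LandmarkLabel] = []
    for l in track.labels:
        t_vis = l.frame_index * cyc + schedule.visible_shutter_ms
        if not l.present and run_len.get(l.frame_index, 0) > max_absent_span:
            out.append(l)
            continue
        if not l.present and not (t_lo <= t_vis <= t_hi):
            out.append(l)
            continue
        out.append(
            LandmarkLabel(
                l.frame_index,
                float(fx(t_vis)),
                float(fy(t_vis)),
                True,
                SOURCE_INTERPOLATED,
            )
        )
    return replace(track, labels=out)
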