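"""Synthetic fixtures: dye sequences, speckle scenes, and mock detectors.

Every generator ships its own ground truth (planted paths, analytic warps,
or known confidence curves) and is bit-reproducible under a fixed seed, so
each pipeline stage can be tested without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skimage.transform import ProjectiveTransform
from skimage.transform import warp as skimage_warp

from .acquisition import (
    TRIPHASIC,
    FrameRecord,
    TriggerSchedule,
    UVVisiblePair,
    build_trigger_schedule,
)
from .barcode import FeatureSet, Match
from .errors import DetectorFailure, InputError
from .evaluation import Prediction
from .serial import LabelTrack, LandmarkLabel

# ---------------------------------------------------------------------------
# serial (dye blob) sequences


@dataclass(frozen=True)
class SerialFixtureSpec:
    """A moving antialiased dye blob over a textured visible scene."""

    n_frames: int = 10
    width: int = 256
    height: int = 256
    blob_radius_px: float = 6.0
    blob_intensity: float = 0.9
    background_intensity: float = 0.02
    texture_amplitude: float = 0.3
    path: str = "linear"  # linear | circular | waypoints
    path_start: tuple[float, float] = (40.0, 40.0)
    path_end: tuple[float, float] = (200.0, 200.0)
    waypoints: tuple[tuple[float, float], ...] = ()
    occlusion_frames: frozenset[int] = frozenset()
    seed: int = 0
    schedule: TriggerSchedule = field(
        default_factory=lambda: build_trigger_schedule(10.0, TRIPHASIC, 2.0, 0.25)
    )


@dataclass
class SerialFixture:
    uv_frames: list[np.ndarray]
    visible_frames: list[np.ndarray]
    truth: LabelTrack
    frames: list[FrameRecord]
    pairs: list[UVVisiblePair]
    spec: SerialFixtureSpec


def _render_blob(
    width: int, height: int, cx: float, cy: float, radius: float, intensity: float
) -> np.ndarray:
    """Antialiased disk: intensity ramps down linearly over the last pixel."""
    ys, xs = np.mgrid[0:height, 0:width]
    dist = np.hypot(xs - cx, ys - cy)
    return intensity * np.clip(radius + 0.5 - dist, 0.0, 1.0)


def blob_path(spec: SerialFixtureSpec) -> np.ndarray:
    """Planted blob centers, one (x, y) row per frame."""
    n = spec.n_frames
    t = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.0])
    if spec.path == "linear":
        x0, y0 = spec.path_start
        x1, y1 = spec.path_end
        return np.column_stack([x0 + t * (x1 - x0), y0 + t * (y1 - y0)])
    if spec.path == "circular":
        cx = (spec.path_start[0] + spec.path_end[0]) / 2
        cy = (spec.path_start[1] + spec.path_end[1]) / 2
        r = math.hypot(spec.path_end[0] - spec.path_start[0],
                       spec.path_end[1] - spec.path_start[1]) / 2
        ang = 2 * math.pi * t
        return np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)])
    if spec.path == "waypoints":
        pts = np.asarray(spec.waypoints, dtype=float)
        if pts.shape[0] < 2:
            raise InputError("waypoints path needs >= 2 points")
        u = t * (pts.shape[0] - 1)
        lo = np.minimum(u.astype(int), pts.shape[0] - 2)
        frac = (u - lo)[:, None]
        return pts[lo] * (1 - frac) + pts[lo + 1] * frac
    raise InputError(f"unknown path type {spec.path!r}")


def gen_serial_sequence(spec: SerialFixtureSpec) -> SerialFixture:
    """Render a UV/visible pair sequence with planted ground truth.

    UV frames contain only the blob over a near-black background (triphasic
    regime); visible frames contain seeded texture without the dye.  The
    truth track holds the planted centers, absent on occlusion frames.
    """
    centers = blob_path(spec)
    margin = spec.blob_radius_px + 1
    for i, (cx, cy) in enumerate(centers):
        if i in spec.occlusion_frames:
            continue
        if not (margin <= cx < spec.width - margin and margin <= cy < spec.height - margin):
            raise InputError(f"blob leaves the frame at frame {i}: ({cx}, {cy})")

    rng = np.random.default_rng(spec.seed)
    texture = spec.background_intensity + spec.texture_amplitude * rng.random(
        (spec.height, spec.width)
    )
    uv_frames, visible_frames, labels, frames, pairs = [], [], [], [], []
    sched = spec.schedule
    for i, (cx, cy) in enumerate(centers):
        uv = np.full((spec.height, spec.width), spec.background_intensity * 0.1)
        if i not in spec.occlusion_frames:
            uv = uv + _render_blob(
                spec.width, spec.height, cx, cy, spec.blob_radius_px, spec.blob_intensity
            )
            labels.append(LandmarkLabel(i, float(cx), float(cy), True))
        else:
            labels.append(LandmarkLabel.absent(i))
        vis = texture + 0.05 * rng.random((spec.height, spec.width))
        uv_frames.append(uv)
        visible_frames.append(vis)
        t0 = i * sched.cycle_ms
        uv_rec = FrameRecord(2 * i, t0 + sched.uv_shutter_ms, "uv")
        vis_rec = FrameRecord(2 * i + 1, t0 + sched.visible_shutter_ms, "visible")
        frames.extend([uv_rec, vis_rec])
        pairs.append(UVVisiblePair(uv=uv_rec, visible=vis_rec))

    # truth labels attach to the visible frame index of each pair
    truth = LabelTrack(
        [
            LandmarkLabel(p.visible.index, l.x, l.y, l.present, l.source)
            for p, l in zip(pairs, labels)
        ],
        width=spec.width,
        height=spec.height,
    )
    return SerialFixture(uv_frames, visible_frames, truth, frames, pairs, spec)


# ---------------------------------------------------------------------------
# speckle scenes under known warps


@dataclass(frozen=True)
class SpeckleFixtureSpec:
    """Gaussian-spot speckle texture observed under known invertible warps."""

    width: int = 256
    height: int = 256
    n_spots: int = 700
    spot_sigma_range: tuple[float, float] = (0.8, 1.4)
    intensity_range: tuple[float, float] = (0.3, 1.0)
    background_noise_amp: float = 0.4
    n_frames: int = 1
    warp: str = "identity"  # identity | translation | affine | projective
    translation: tuple[float, float] = (0.0, 0.0)
    matrix: tuple[tuple[float, float, float], ...] = ()
    foreground: str = "full"  # full | ellipse
    ellipse_center: tuple[float, float] = (128.0, 128.0)
    ellipse_axes: tuple[float, float] = (90.0, 60.0)
    seed: int = 0


@dataclass
class SpeckleScene:
    template: np.ndarray
    frames: list[np.ndarray]
    correspondences: list[Callable[[np.ndarray], np.ndarray]]
    matrices: list[np.ndarray]
    foreground_masks: list[np.ndarray]
    spot_centers: np.ndarray
    spec: SpeckleFixtureSpec


def _warp_matrix(spec: SpeckleFixtureSpec, frame: int) -> np.ndarray:
    if spec.warp == "identity":
        return np.eye(3)
    if spec.warp == "translation":
        m = np.eye(3)
        m[0, 2], m[1, 2] = spec.translation
        return m
    if spec.warp in ("affine", "projective"):
        if not spec.matrix:
            raise InputError(f"{spec.warp} warp requires an explicit matrix")
        m = np.asarray(spec.matrix, dtype=float)
        if m.shape != (3, 3):
            raise InputError("warp matrix must be 3x3")
        if abs(np.linalg.det(m)) < 1e-12:
            raise InputError("warp matrix is not invertible")
        return m
    raise InputError(f"unknown warp type {spec.warp!r}")


def apply_homography(matrix: np.ndarray, points: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    hom = np.column_stack([pts, np.ones(len(pts))]) @ matrix.T
    return hom[:, :2] / hom[:, 2:]


def _render_spots(
    shape: tuple[int, int],
    centers: np.ndarray,
    sigmas: np.ndarray,
    intensities: np.ndarray,
) -> np.ndarray:
    h, w = shape
    img = np.zeros(shape, dtype=float)
    for (cx, cy), s, a in zip(centers, sigmas, intensities):
        r = int(math.ceil(4 * s))
        x0, x1 = int(cx) - r, int(cx) + r + 1
        y0, y1 = int(cy) - r, int(cy) + r + 1
        x0c, x1c = max(0, x0), min(w, x1)
        y0c, y1c = max(0, y0), min(h, y1)
        if x0c >= x1c or y0c >= y1c:
            continue
        ys, xs = np.mgrid[y0c:y1c, x0c:x1c]
        img[y0c:y1c, x0c:x1c] += a * np.exp(
            -((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * s * s)
        )
    return np.clip(img, 0.0, 1.0)


def _foreground_mask(spec: SpeckleFixtureSpec, matrix: np.ndarray) -> np.ndarray:
    """Analytic raster of the foreground region under the frame warp."""
    shape = (spec.height, spec.width)
    if spec.foreground == "full":
        return np.ones(shape, dtype=bool)
    inv = np.linalg.inv(matrix)
    ys, xs = np.mgrid[0 : spec.height, 0 : spec.width]
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    back = apply_homography(inv, pts)
    cx, cy = spec.ellipse_center
    ax, ay = spec.ellipse_axes
    inside = ((back[:, 0] - cx) / ax) ** 2 + ((back[:, 1] - cy) / ay) ** 2 <= 1
    return inside.reshape(shape)


def gen_speckle_scene(spec: SpeckleFixtureSpec) -> SpeckleScene:
    """Render a speckle template plus warped frames with exact correspondence.

    The base texture is antialiased Gaussian spots (hard disks alias under
    warps) over low-amplitude multi-scale background noise, which keeps each
    neighborhood globally distinctive.  Frame ``t`` resamples the base
    texture through ``warp_t`` (identity warps reuse the base verbatim); the
    correspondence function is the stored 3x3 matrix applied analytically.
    """
    rng = np.random.default_rng(spec.seed)
    margin = 8.0
    if spec.foreground == "ellipse":
        cx, cy = spec.ellipse_center
        ax, ay = spec.ellipse_axes
        centers = np.empty((0, 2))
        while len(centers) < spec.n_spots:
            cand = np.column_stack(
                [
                    rng.uniform(cx - ax, cx + ax, spec.n_spots),
                    rng.uniform(cy - ay, cy + ay, spec.n_spots),
                ]
            )
            inside = ((cand[:, 0] - cx) / ax) ** 2 + ((cand[:, 1] - cy) / ay) ** 2 <= 1
            centers = np.vstack([centers, cand[inside]])
        centers = centers[: spec.n_spots]
    elif spec.foreground == "full":
        centers = np.column_stack(
            [
                rng.uniform(margin, spec.width - margin, spec.n_spots),
                rng.uniform(margin, spec.height - margin, spec.n_spots),
            ]
        )
    else:
        raise InputError(f"unknown foreground type {spec.foreground!r}")
    sigmas = rng.uniform(*spec.spot_sigma_range, spec.n_spots)
    intensities = rng.uniform(*spec.intensity_range, spec.n_spots)
    shape = (spec.height, spec.width)
    template = _render_spots(shape, centers, sigmas, intensities)
    if spec.background_noise_amp > 0:
        from .propagation import multiscale_noise

        template = template + spec.background_noise_amp * multiscale_noise(
            shape, spec.seed + 7919
        )
    template = np.clip(template, 0.0, 1.0)

    frames, correspondences, matrices, fg_masks = [], [], [], []
    for t in range(spec.n_frames):
        m = _warp_matrix(spec, t)
        if np.allclose(m, np.eye(3)):
            frames.append(template.copy())
        else:
            frames.append(
                skimage_warp(
                    template,
                    ProjectiveTransform(matrix=m).inverse,
                    order=3,
                    preserve_range=True,
                )
            )
        matrices.append(m)
        correspondences.append(lambda p, _m=m: apply_homography(_m, p))
        fg_masks.append(_foreground_mask(spec, m))
    return SpeckleScene(
        template=template,
        frames=frames,
        correspondences=correspondences,
        matrices=matrices,
        foreground_masks=fg_masks,
        spot_centers=centers,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# synthetic match configurations (feature-level plants)


def gen_coherent_matches(
    n_true: int,
    n_spurious: int,
    seed: int = 0,
    canvas: tuple[float, float] = (300.0, 300.0),
    matrix: np.ndarray | None = None,
) -> tuple[list[Match], np.ndarray]:
    """Plant coherent true matches under a smooth warp plus isolated spurious ones.

    True left endpoints are grid-jittered (dense enough that every true match
    has a coherent neighbor under the default 50 px radii); right endpoints
    follow a mild homography.  Spurious matches get independent random
    endpoints on both sides.  Returns the matches (true first) and a boolean
    array marking the true ones.
    """
    rng = np.random.default_rng(seed)
    w, h = canvas
    ncol = int(math.ceil(math.sqrt(n_true * w / h)))
    nrow = int(math.ceil(n_true / ncol))
    gx = np.linspace(10, w - 10, ncol)
    gy = np.linspace(10, h - 10, nrow)
    grid = np.array([(x, y) for y in gy for x in gx])[:n_true]
    left = grid + rng.uniform(-4, 4, grid.shape)
    if matrix is None:
        ang = rng.uniform(-0.1, 0.1)
        s = rng.uniform(0.95, 1.05)
        tx, ty = rng.uniform(-20, 20, 2)
        matrix = np.array(
            [
                [s * math.cos(ang), -s * math.sin(ang), tx],
                [s * math.sin(ang), s * math.cos(ang), ty],
                [0, 0, 1],
            ]
        )
    right = apply_homography(matrix, left)
    matches = [
        Match(i, i, (float(lx), float(ly)), (float(rx), float(ry)), 0.1)
        for i, ((lx, ly), (rx, ry)) in enumerate(zip(left, right))
    ]
    # spurious: both endpoints independent and far from the true cloud
    for k in range(n_spurious):
        lx, ly = rng.uniform(w + 100, w + 2000), rng.uniform(h + 100, h + 2000)
        rx, ry = rng.uniform(-2000, -100), rng.uniform(-2000, -100)
        matches.append(
            Match(n_true + k, n_true + k, (float(lx), float(ly)), (float(rx), float(ry)), 0.9)
        )
    is_true = np.zeros(len(matches), dtype=bool)
    is_true[:n_true] = True
    return matches, is_true


def gen_synthetic_corpus(
    n_images: int,
    n_patterns: int,
    features_per_image: tuple[int, int],
    seed: int = 0,
    descriptor_len: int = 32,
    canvas: float = 300.0,
) -> list[FeatureSet]:
    """Descriptor-level corpus for atlas tests: shared patterns across images.

    Each of ``n_patterns`` underlying speckle patterns has a prototype
    descriptor and a home position; an image contains a random subset of
    patterns, each rendered as the prototype plus small noise at its home
    position plus small jitter, so same-pattern features match across images
    and stay spatially coherent.
    """
    rng = np.random.default_rng(seed)
    prototypes = rng.uniform(0, 100, (n_patterns, descriptor_len))
    homes = rng.uniform(10, canvas - 10, (n_patterns, 2))
    corpus = []
    lo, hi = features_per_image
    for i in range(n_images):
        k = int(rng.integers(lo, hi + 1))
        patterns = rng.choice(n_patterns, size=min(k, n_patterns), replace=False)
        desc = prototypes[patterns] + rng.normal(0, 0.5, (len(patterns), descriptor_len))
        xy = homes[patterns] + rng.normal(0, 2.0, (len(patterns), 2))
        kp = np.column_stack([xy, np.ones(len(patterns)), np.zeros(len(patterns))])
        corpus.append(FeatureSet(f"img{i:03d}", kp, desc))
    return corpus


# ---------------------------------------------------------------------------
# mock detectors


@dataclass(frozen=True)
class MockDetectorSpec:
    """Truth-plus-noise detector with a unimodal confidence-vs-scale curve."""

    truth: tuple[tuple[float, float], ...]  # (x, y) per frame
    noise_sigma_px: float = 0.0
    peak_scale: float = 1.0
    log_width: float = 0.3  # Gaussian width of the confidence curve in log2 scale
    per_frame_peak_scales: tuple[float, ...] = ()
    failure_frames: frozenset[int] = frozenset()
    seed: int = 0


def gen_mock_detector(spec: MockDetectorSpec) -> Callable[[int, float], Prediction]:
    """Build a detector closure honoring the adapter contract.

    The detector takes ``(frame_index, scale)`` and returns a
    :class:`Prediction` in original-image coordinates; positional noise is
    drawn once per frame at construction, so predictions are scale-invariant
    and fully deterministic.
    """
    rng = np.random.default_rng(spec.seed)
    truth = np.asarray(spec.truth, dtype=float)
    noise = rng.normal(0, spec.noise_sigma_px, truth.shape) if spec.noise_sigma_px else np.zeros(truth.shape)

    def confidence(frame_index: int, scale: float) -> float:
        peak = (
            spec.per_frame_peak_scales[frame_index]
            if spec.per_frame_peak_scales
            else spec.peak_scale
        )
        z = (math.log2(scale) - math.log2(peak)) / spec.log_width
        return float(math.exp(-z * z / 2))

    def detector(frame_index: int, scale: float) -> Prediction:
        if frame_index in spec.failure_frames:
            raise DetectorFailure(f"planted failure at frame {frame_index}")
        if scale <= 0:
            raise DetectorFailure("non-positive scale")
        x, y = truth[frame_index] + noise[frame_index]
        return Prediction(frame_index, float(x), float(y), confidence(frame_index, scale))

    return detector
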