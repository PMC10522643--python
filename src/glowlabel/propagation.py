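"""Label propagation, training targets, masks, augmentation, and export.

Filtered barcode matches become landmark labels two ways: manual-neighborhood
median pooling (per hand-drawn template region) or automatic-neighborhood
propagation, where a spacing-constrained landmark feature that fails to match
is recovered by fitting a local homography to its matched neighbors.
Downstream helpers build stride-reduced training targets with loss masks,
foreground segmentation masks, background composites, and geometric
augmentations, and export datasets as CSV or COCO keypoints JSON.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.morphology import closing, dilation, disk
from skimage.transform import AffineTransform, ProjectiveTransform, resize, warp

from .barcode import FeatureSet, Match
from .errors import ExportError, InputError
from .serial import (
    SOURCE_DETECTOR,
    SOURCE_PROPAGATED,
    LandmarkLabel,
)


@dataclass(frozen=True)
class NeighborhoodLabelConfig:
    """Pooling rule for manual template neighborhoods."""

    min_matches: int = 5
    pool_statistic: str = "median"

    def __post_init__(self):
        if self.min_matches < 1:
            raise ValueError("min_matches must be >= 1")
        if self.pool_statistic != "median":
            raise ValueError("only median pooling is supported")


@dataclass(frozen=True)
class AutoLandmarkConfig:
    """Automatic landmark selection and homography propagation parameters.

    ``robust_trim_px`` enables one residual-trimmed refit: supports whose
    residual under the initial fit exceeds ``max(robust_trim_px, 3 * median
    residual)`` are dropped before the final fit (0 disables).
    ``min_support_sv_px`` guards conditioning: when the trimmed support
    cloud's smaller RMS extent falls below it, the perspective terms are
    unidentifiable and an affine fit (a restricted homography) is used.
    """

    min_spacing_px: float = 30.0
    neighborhood_radius_px: float = 30.0
    min_neighbors: int = 10
    seed: int = 0
    robust_trim_px: float = 2.5
    min_support_sv_px: float = 6.0

    def __post_init__(self):
        if self.min_spacing_px <= 0 or self.neighborhood_radius_px <= 0:
            raise ValueError("spacing and radius must be positive")
        if self.min_neighbors < 4:
            # a homography needs 4 non-degenerate correspondences
            raise ValueError("min_neighbors must be >= 4")


@dataclass(frozen=True)
class TrainingTargetConfig:
    """Geometry of the stride-reduced training target maps."""

    stride: int = 8
    positive_radius_px: float = 17.0
    landmark_roster: tuple[str, ...] = ()

    def __post_init__(self):
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


# ---------------------------------------------------------------------------
# manual neighborhoods


def pool_manual_neighborhood(
    matches_by_region: Mapping[int, Sequence[Match]],
    cfg: NeighborhoodLabelConfig = NeighborhoodLabelConfig(),
    frame_index: int = 0,
) -> dict[int, LandmarkLabel]:
    """Pool filtered matches per region into one label per region.

    A region with at least ``min_matches`` matches gets the per-axis median
    of the right-endpoint coordinates; otherwise it is recorded absent.
    When several templates supply a region, concatenate their matches before
    calling (pooling happens before the count check).
    """
    labels: dict[int, LandmarkLabel] = {}
    for region, matches in matches_by_region.items():
        if len(matches) >= cfg.min_matches:
            xs = np.array([m.right_xy[0] for m in matches])
            ys = np.array([m.right_xy[1] for m in matches])
            labels[region] = LandmarkLabel(
                frame_index,
                float(np.median(xs)),
                float(np.median(ys)),
                True,
                SOURCE_DETECTOR,
            )
        else:
            labels[region] = LandmarkLabel.absent(frame_index, SOURCE_DETECTOR)
    return labels


def group_matches_by_region(
    matches: Sequence[Match], template_regions: np.ndarray
) -> dict[int, list[Match]]:
    """Bucket matches by the template region under their left endpoint."""
    regions = np.asarray(template_regions)
    if regions.ndim != 2:
        raise InputError("region mask must be 2-D")
    h, w = regions.shape
    grouped: dict[int, list[Match]] = {
        int(r): [] for r in np.unique(regions) if r != 0
    }
    for m in matches:
        col, row = int(round(m.left_xy[0])), int(round(m.left_xy[1]))
        if 0 <= row < h and 0 <= col < w and regions[row, col] != 0:
            grouped[int(regions[row, col])].append(m)
    return grouped


# ---------------------------------------------------------------------------
# automatic neighborhoods


@dataclass
class AutoLandmarks:
    """Spacing-constrained landmark features with their support neighbors."""

    landmark_indices: list[int]
    neighbor_lists: dict[int, list[int]]
    template: FeatureSet


def select_auto_landmarks(
    template_features: FeatureSet,
    cfg: AutoLandmarkConfig = AutoLandmarkConfig(),
    candidate_mask: np.ndarray | None = None,
) -> AutoLandmarks:
    """Pick landmark features at least ``min_spacing_px`` apart.

    Candidates are visited in a seeded random order; a candidate is kept when
    it is at least the minimum spacing away from every already-kept landmark,
    which makes the selection a maximal packing.  ``candidate_mask``
    optionally restricts candidates to a region (nonzero pixels).  Each
    landmark's neighbor list holds *all* template features (selected or not,
    excluding itself) within the neighborhood radius.
    """
    xy = template_features.xy
    candidates = np.arange(len(template_features))
    if candidate_mask is not None:
        mask = np.asarray(candidate_mask)
        h, w = mask.shape
        inside = []
        for i in candidates:
            col, row = int(round(xy[i, 0])), int(round(xy[i, 1]))
            if 0 <= row < h and 0 <= col < w and mask[row, col]:
                inside.append(i)
        candidates = np.array(inside, dtype=int)
    if candidates.size == 0:
        return AutoLandmarks([], {}, template_features)

    rng = np.random.default_rng(cfg.seed)
    order = candidates[rng.permutation(candidates.size)]
    selected: list[int] = []
    for i in order:
        p = xy[i]
        if all(np.hypot(*(p - xy[j])) >= cfg.min_spacing_px for j in selected):
            selected.append(int(i))

    tree = cKDTree(xy)
    neighbor_lists: dict[int, list[int]] = {}
    for i in selected:
        near = tree.query_ball_point(xy[i], cfg.neighborhood_radius_px)
        neighbor_lists[i] = sorted(j for j in near if j != i)
    return AutoLandmarks(selected, neighbor_lists, template_features)


def _fit_local_homography(
    src: np.ndarray, dst: np.ndarray, cfg: AutoLandmarkConfig
) -> ProjectiveTransform | AffineTransform | None:
    """Least-squares local homography with optional trim and affine fallback."""
    tform = ProjectiveTransform.from_estimate(src, dst)
    if not tform or not np.all(np.isfinite(tform.params)):
        return None
    if cfg.robust_trim_px > 0:
        resid = np.hypot(*(tform(src) - dst).T)
        keep = resid <= max(cfg.robust_trim_px, 3 * float(np.median(resid)))
        if 4 <= keep.sum() < len(src):
            src, dst = src[keep], dst[keep]
    # RMS extents of the support cloud; (near-)collinear supports cannot
    # identify any homography, and a merely thin cloud cannot identify the
    # perspective terms, so fall back to the affine submodel
    sv = np.linalg.svd(src - src.mean(axis=0), compute_uv=False) / math.sqrt(len(src))
    if sv[-1] < 1e-3:
        return None
    cls = AffineTransform if sv[-1] < cfg.min_support_sv_px else ProjectiveTransform
    tform = cls.from_estimate(src, dst)
    if not tform or not np.all(np.isfinite(tform.params)):
        return None
    return tform


def propagate_landmark(
    landmark_index: int,
    neighbor_indices: Sequence[int],
    template_features: FeatureSet,
    frame_matches: Sequence[Match],
    cfg: AutoLandmarkConfig = AutoLandmarkConfig(),
    frame_index: int = 0,
) -> LandmarkLabel:
    """Label one landmark in one target frame.

    If the landmark feature itself matched, its match location is the label.
    Otherwise, if at least ``min_neighbors`` of its neighbors matched, a
    local homography fit to those neighbor correspondences (least-squares
    DLT with one residual-trimmed refit; see :class:`AutoLandmarkConfig`)
    maps the landmark's template position into the target.  Degenerate
    support geometry falls through to an absent label with a warning.
    """
    by_left = {m.left_index: m for m in frame_matches}
    direct = by_left.get(landmark_index)
    if direct is not None:
        return LandmarkLabel(
            frame_index, direct.right_xy[0], direct.right_xy[1], True, SOURCE_DETECTOR
        )
    support = [by_left[j] for j in neighbor_indices if j in by_left]
    if len(support) < cfg.min_neighbors:
        return LandmarkLabel.absent(frame_index, SOURCE_PROPAGATED)
    src = np.array([m.left_xy for m in support])
    dst = np.array([m.right_xy for m in support])
    tform = _fit_local_homography(src, dst, cfg)
    if tform is None:
        warnings.warn(
            f"degenerate homography support for landmark {landmark_index}",
            stacklevel=2,
        )
        return LandmarkLabel.absent(frame_index, SOURCE_PROPAGATED)
    x, y = tform(template_features.xy[landmark_index][None, :])[0]
    if not (math.isfinite(x) and math.isfinite(y)):
        return LandmarkLabel.absent(frame_index, SOURCE_PROPAGATED)
    return LandmarkLabel(frame_index, float(x), float(y), True, SOURCE_PROPAGATED)


def propagate_frame(
    landmarks: AutoLandmarks,
    frame_matches: Sequence[Match],
    cfg: AutoLandmarkConfig = AutoLandmarkConfig(),
    frame_index: int = 0,
    use_homography: bool = True,
) -> dict[int, LandmarkLabel]:
    """Propagate every selected landmark into one target frame.

    ``use_homography=False`` keeps only direct matches (the ablated variant).
    """
    out: dict[int, LandmarkLabel] = {}
    for i in landmarks.landmark_indices:
        if use_homography:
            out[i] = propagate_landmark(
                i, landmarks.neighbor_lists[i], landmarks.template,
                frame_matches, cfg, frame_index,
            )
        else:
            by_left = {m.left_index: m for m in frame_matches}
            direct = by_left.get(i)
            out[i] = (
                LandmarkLabel(
                    frame_index, direct.right_xy[0], direct.right_xy[1],
                    True, SOURCE_DETECTOR,
                )
                if direct is not None
                else LandmarkLabel.absent(frame_index, SOURCE_DETECTOR)
            )
    return out


# ---------------------------------------------------------------------------
# segmentation and background compositing


def make_segmentation_mask(
    uv_speckle_image: np.ndarray,
    dilation_px: int = 2,
    closing_px: int = 15,
    threshold: float | str = "otsu",
) -> np.ndarray:
    """Fuse speckle responses into a solid foreground mask.

    Thresholded speckles are morphologically closed into a solid region,
    interior holes are filled, and the result is dilated by ``dilation_px``.
    """
    img = np.asarray(uv_speckle_image, dtype=float)
    if img.ndim != 2:
        raise InputError("UV image must be single-channel")
    if isinstance(threshold, str):
        if img.max() <= img.min():
            return np.zeros(img.shape, dtype=bool)
        thr = float(threshold_otsu(img))
    else:
        thr = float(threshold)
    mask = img >= thr
    if not mask.any():
        return mask
    if closing_px > 0:
        mask = closing(mask, disk(closing_px))
    mask = ndimage.binary_fill_holes(mask)
    if dilation_px > 0:
        mask = dilation(mask, disk(dilation_px))
    return mask


def multiscale_noise(shape: tuple[int, int], seed: int, n_octaves: int = 4) -> np.ndarray:
    """Seeded background noise mixing low and high spatial frequencies."""
    rng = np.random.default_rng(seed)
    h, w = shape
    out = np.zeros(shape, dtype=float)
    for octave in range(n_octaves):
        step = 2 ** (n_octaves - octave)
        coarse = rng.random((max(1, h // step), max(1, w // step)))
        out += resize(coarse, shape, order=1, anti_aliasing=False) / (octave + 1)
    out -= out.min()
    peak = out.max()
    return out / peak if peak > 0 else out


def composite_background(
    visible_image: np.ndarray,
    mask: np.ndarray,
    background: np.ndarray | Mapping | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Replace background pixels, preserving foreground pixels exactly.

    ``background`` may be an image of matching size, a spec mapping
    (``{"type": "constant", "value": v}`` or ``{"type": "noise"}``), or None
    for seeded multi-scale noise.
    """
    img = np.asarray(visible_image, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if m.shape != img.shape[:2]:
        raise InputError("mask and image sizes differ")
    if background is None:
        bg = multiscale_noise(img.shape[:2], seed)
    elif isinstance(background, Mapping):
        kind = background.get("type", "noise")
        if kind == "constant":
            bg = np.full(img.shape[:2], float(background["value"]))
        elif kind == "noise":
            bg = multiscale_noise(img.shape[:2], seed)
        else:
            raise InputError(f"unknown background spec type {kind!r}")
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape[:2] != img.shape[:2]:
            raise InputError("background and image sizes differ")
    if img.ndim == 3 and bg.ndim == 2:
        bg = bg[..., None] * np.ones(img.shape[2])
    out = np.where(m[..., None] if img.ndim == 3 else m, img, bg)
    return out


# ---------------------------------------------------------------------------
# training targets


def make_training_targets(
    labels: Mapping[str, LandmarkLabel],
    image_size: tuple[int, int],
    cfg: TrainingTargetConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Build per-landmark confidence targets and the channel loss mask.

    Returns ``(targets, loss_mask)`` with targets of shape
    ``(n_landmarks, ceil(h/stride), ceil(w/stride))``.  A present label
    produces a disk of ones of ``positive_radius_px`` (input-pixel units)
    around its position; a label recorded absent produces an all-zeros map
    that *does* contribute to the loss (mask 1); roster landmarks with no
    label at all get loss mask 0 (interleaved training).
    """
    h, w = image_size
    if not cfg.landmark_roster:
        raise InputError("landmark roster is empty")
    mh = math.ceil(h / cfg.stride)
    mw = math.ceil(w / cfg.stride)
    targets = np.zeros((len(cfg.landmark_roster), mh, mw), dtype=float)
    loss_mask = np.zeros(len(cfg.landmark_roster), dtype=float)
    # map-cell centers in input coordinates
    cols = (np.arange(mw) + 0.5) * cfg.stride - 0.5
    rows = (np.arange(mh) + 0.5) * cfg.stride - 0.5
    for c, name in enumerate(cfg.landmark_roster):
        label = labels.get(name)
        if label is None:
            continue  # unlabeled in this image: loss mask stays 0
        loss_mask[c] = 1.0
        if not label.present:
            continue  # absent: all-zeros target, supervised
        if not (0 <= label.x < w and 0 <= label.y < h):
            raise InputError(
                f"label for {name!r} at ({label.x}, {label.y}) outside image"
            )
        dist2 = (cols[None, :] - label.x) ** 2 + (rows[:, None] - label.y) ** 2
        targets[c] = (dist2 <= cfg.positive_radius_px**2).astype(float)
    return targets, loss_mask


# ---------------------------------------------------------------------------
# augmentation


@dataclass(frozen=True)
class AugmentConfig:
    """Ranges of the per-image augmentation draw.

    Each geometric transform is drawn once per image and applied identically
    to image and labels.  Collapsing every range to its neutral point yields
    the identity.
    """

    blur_sigma: tuple[float, float] = (0.0, 0.5)
    contrast: tuple[float, float] = (0.75, 1.5)
    noise_sigma_frac: float = 0.05
    channel_scale: tuple[float, float] = (0.8, 1.2)
    crop_frac: tuple[float, float] = (0.0, 0.1)
    affine_scale: tuple[float, float] = (0.8, 1.2)
    translate_x_frac: tuple[float, float] = (-0.05, 0.05)
    translate_y_frac: tuple[float, float] = (-0.05, 0.05)
    rotation_deg: tuple[float, float] = (-15.0, 15.0)
    shear_deg: tuple[float, float] = (-8.0, 8.0)
    grayscale_prob: float = 0.5

    @classmethod
    def identity(cls) -> "AugmentConfig":
        return cls(
            blur_sigma=(0.0, 0.0),
            contrast=(1.0, 1.0),
            noise_sigma_frac=0.0,
            channel_scale=(1.0, 1.0),
            crop_frac=(0.0, 0.0),
            affine_scale=(1.0, 1.0),
            translate_x_frac=(0.0, 0.0),
            translate_y_frac=(0.0, 0.0),
            rotation_deg=(0.0, 0.0),
            shear_deg=(0.0, 0.0),
            grayscale_prob=0.0,
        )


def _uniform(rng: np.random.Generator, lo_hi: tuple[float, float]) -> float:
    lo, hi = lo_hi
    return lo if lo == hi else float(rng.uniform(lo, hi))


def augment_image(
    image: np.ndarray,
    labels: Sequence[LandmarkLabel],
    seed: int,
    cfg: AugmentConfig = AugmentConfig(),
) -> tuple[np.ndarray, list[LandmarkLabel]]:
    """One seeded random draw of the augmentation menu.

    Photometric perturbations (blur, contrast, noise, channel scale,
    grayscale) touch only the image; the affine warp and crop transform the
    labels identically, and labels that leave the frame become absent.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    img = np.asarray(image, dtype=float).copy()
    h, w = img.shape[:2]

    # --- geometric draw
    scale = _uniform(rng, cfg.affine_scale)
    tx = _uniform(rng, cfg.translate_x_frac) * w
    ty = _uniform(rng, cfg.translate_y_frac) * h
    rot = math.radians(_uniform(rng, cfg.rotation_deg))
    shear = math.radians(_uniform(rng, cfg.shear_deg))
    crop = _uniform(rng, cfg.crop_frac)

    is_identity = (
        scale == 1.0 and tx == 0.0 and ty == 0.0 and rot == 0.0 and shear == 0.0
    )
    if not is_identity:
        center = AffineTransform(translation=(-w / 2, -h / 2))
        core = AffineTransform(scale=scale, rotation=rot, shear=shear)
        uncenter = AffineTransform(translation=(w / 2 + tx, h / 2 + ty))
        tform = center + core + uncenter
        img = warp(img, tform.inverse, order=1, preserve_range=True)
    else:
        tform = None

    new_labels: list[LandmarkLabel] = []
    for l in labels:
        if not l.present:
            new_labels.append(l)
            continue
        x, y = (tform([[l.x, l.y]])[0] if tform is not None else (l.x, l.y))
        new_labels.append(LandmarkLabel(l.frame_index, float(x), float(y), True, l.source))

    if crop > 0:
        # symmetric crop then resize back, labels rescaled accordingly
        cy, cx = int(round(h * crop / 2)), int(round(w * crop / 2))
        if cy > 0 or cx > 0:
            img = img[cy : h - cy, cx : w - cx]
            ch, cw = img.shape[:2]
            img = resize(img, (h, w) + img.shape[2:], order=1, preserve_range=True)
            sx, sy = w / cw, h / ch
            new_labels = [
                LandmarkLabel(
                    l.frame_index, (l.x - cx) * sx, (l.y - cy) * sy, True, l.source
                )
                if l.present
                else l
                for l in new_labels
            ]

    # out-of-frame labels become absent
    new_labels = [
        l
        if not l.present or (0 <= l.x < w and 0 <= l.y < h)
        else LandmarkLabel.absent(l.frame_index, l.source)
        for l in new_labels
    ]

    # --- photometric draw
    sigma = _uniform(rng, cfg.blur_sigma)
    if sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=(sigma, sigma) + (0,) * (img.ndim - 2))
    contrast = _uniform(rng, cfg.contrast)
    if contrast != 1.0:
        mean = img.mean()
        img = (img - mean) * contrast + mean
    if cfg.noise_sigma_frac > 0:
        peak = max(img.max(), 1e-12)
        img = img + rng.normal(0, cfg.noise_sigma_frac * peak, img.shape)
    if img.ndim == 3:
        cs = np.array([_uniform(rng, cfg.channel_scale) for _ in range(img.shape[2])])
        if np.any(cs != 1.0):
            img = img * cs
        if cfg.grayscale_prob > 0 and rng.random() < cfg.grayscale_prob:
            img = np.repeat(img.mean(axis=2, keepdims=True), img.shape[2], axis=2)
    return img, new_labels


# ---------------------------------------------------------------------------
# dataset export


def export_dataset(
    images: Sequence[Mapping],
    labels: Mapping[str, Mapping[str, LandmarkLabel]],
    roster: Sequence[str],
    path,
    format: str = "coco_keypoints",
) -> None:
    """Write a labeled dataset to disk.

    ``images`` is a sequence of mappings with keys ``id``, ``file_name``,
    ``width``, ``height``; ``labels`` maps image id to a mapping of landmark
    name to label.  COCO keypoints use visibility 2 for present and 0 (with
    coordinates (0, 0)) for absent.  Exports round-trip byte-identically.
    """
    ids = [str(im["id"]) for im in images]
    if len(set(ids)) != len(ids):
        raise ExportError("duplicate image ids")
    if format == "coco_keypoints":
        doc = {
            "categories": [
                {"id": 1, "name": "subject", "keypoints": list(roster)}
            ],
            "images": [
                {
                    "id": str(im["id"]),
                    "file_name": str(im.get("file_name", "")),
                    "width": int(im["width"]),
                    "height": int(im["height"]),
                }
                for im in images
            ],
            "annotations": [],
        }
        for k, im in enumerate(images):
            img_labels = labels.get(str(im["id"]), {})
            kp: list[float] = []
            n_present = 0
            for name in roster:
                l = img_labels.get(name)
                if l is not None and l.present:
                    kp.extend([float(l.x), float(l.y), 2])
                    n_present += 1
                else:
                    kp.extend([0.0, 0.0, 0])
            doc["annotations"].append(
                {
                    "id": k + 1,
                    "image_id": str(im["id"]),
                    "category_id": 1,
                    "keypoints": kp,
                    "num_keypoints": n_present,
                }
            )
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "csv":
        rows = []
        for im in images:
            img_labels = labels.get(str(im["id"]), {})
            for name in roster:
                l = img_labels.get(name)
                rows.append(
                    {
                        "image_id": str(im["id"]),
                        "landmark": name,
                        "x": l.x if l is not None and l.present else float("nan"),
                        "y": l.y if l is not None and l.present else float("nan"),
                        "present": bool(l is not None and l.present),
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ExportError(f"unknown export format {format!r}")


def import_coco_dataset(path):
    """Read back a COCO keypoints export into (images, labels, roster)."""
    with open(path) as fh:
        doc = json.load(fh)
    roster = list(doc["categories"][0]["keypoints"])
    images = [
        {
            "id": str(im["id"]),
            "file_name": im["file_name"],
            "width": im["width"],
            "height": im["height"],
        }
        for im in doc["images"]
    ]
    labels: dict[str, dict[str, LandmarkLabel]] = {}
    for ann in doc["annotations"]:
        img_id = str(ann["image_id"])
        kp = ann["keypoints"]
        per = {}
        for j, name in enumerate(roster):
            x, y, v = kp[3 * j : 3 * j + 3]
            per[name] = (
                LandmarkLabel(0, float(x), float(y), True)
                if v == 2
                else LandmarkLabel.absent(0)
            )
        labels[img_id] = per
    return images, labels, roster
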