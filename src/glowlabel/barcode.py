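"""Speckle barcode detection, matching, and spatial-coherency filtering.

A speckle of dye forms a locally distinctive texture; SIFT keypoints over it
act as visual barcodes that can be matched between frames.  Putative
descriptor matches are then pruned with a spatial-coherency rule: a match
survives only if some *other* match has its left endpoint within ``delta``
pixels and its right endpoint within ``epsilon`` pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.feature import SIFT

from .errors import InputError

DEFAULT_CONTRAST_THRESHOLD = 0.01


@dataclass
class FeatureSet:
    """Keypoints plus descriptors for one image.

    ``keypoints`` is an (n, 4) float array of (x, y, scale, orientation);
    ``descriptors`` is an (n, d) array, one row per keypoint.
    """

    image_id: str
    keypoints: np.ndarray
    descriptors: np.ndarray

    def __post_init__(self):
        self.keypoints = np.atleast_2d(np.asarray(self.keypoints, dtype=float))
        self.descriptors = np.atleast_2d(np.asarray(self.descriptors, dtype=float))
        if self.keypoints.size == 0:
            self.keypoints = np.empty((0, 4))
        if self.descriptors.size == 0:
            self.descriptors = np.empty((0, self.descriptors.shape[-1] or 128))
        if self.keypoints.shape[0] != self.descriptors.shape[0]:
            raise InputError("keypoint/descriptor count mismatch")

    def __len__(self) -> int:
        return self.keypoints.shape[0]

    @property
    def xy(self) -> np.ndarray:
        return self.keypoints[:, :2]

    @classmethod
    def empty(cls, image_id: str, descriptor_len: int = 128) -> "FeatureSet":
        return cls(image_id, np.empty((0, 4)), np.empty((0, descriptor_len)))


@dataclass(frozen=True)
class Match:
    """One putative correspondence between two feature sets."""

    left_index: int
    right_index: int
    left_xy: tuple[float, float]
    right_xy: tuple[float, float]
    descriptor_distance: float


@dataclass(frozen=True)
class MatchConfig:
    """Putative-match acceptance rule: Lowe ratio plus mutual consistency."""

    ratio: float = 0.75
    mutual: bool = True


@dataclass(frozen=True)
class CoherencyConfig:
    """Radii of the coherency rule: delta on the left, epsilon on the right."""

    delta_px: float = 50.0
    epsilon_px: float = 50.0

    def __post_init__(self):
        if self.delta_px <= 0 or self.epsilon_px <= 0:
            raise ValueError("delta and epsilon must be positive")


def detect_features(
    image: np.ndarray,
    contrast_threshold: float = DEFAULT_CONTRAST_THRESHOLD,
    image_id: str = "",
) -> FeatureSet:
    """Detect SIFT keypoints and descriptors on a single-channel image.

    Deterministic for a fixed image and threshold.  A featureless image
    yields an empty set rather than an error.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InputError("expected a single-channel image")
    sift = SIFT(c_dog=contrast_threshold)
    try:
        sift.detect_and_extract(img)
    except RuntimeError:
        return FeatureSet.empty(image_id)
    rows, cols = sift.keypoints[:, 0], sift.keypoints[:, 1]
    kp = np.column_stack(
        [cols.astype(float), rows.astype(float), sift.sigmas, sift.orientations]
    )
    return FeatureSet(image_id, kp, sift.descriptors.astype(float))


def match_features(
    a: FeatureSet,
    b: FeatureSet,
    cfg: MatchConfig = MatchConfig(),
) -> list[Match]:
    """Nearest-descriptor matching from ``a`` into ``b``.

    Each left keypoint yields at most one match, accepted when it passes the
    Lowe ratio test (distance to best / distance to second-best < ratio) and,
    if configured, the mutual-nearest-neighbor check.  Exact duplicates
    (distance 0) are always accepted.
    """
    if len(a) == 0 or len(b) == 0:
        return []
    if a.descriptors.shape[1] != b.descriptors.shape[1]:
        raise InputError("descriptor lengths differ")
    tree_b = cKDTree(b.descriptors)
    k = min(2, len(b))
    dist, idx = tree_b.query(a.descriptors, k=k)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    if cfg.mutual:
        tree_a = cKDTree(a.descriptors)
        _, back = tree_a.query(b.descriptors, k=1)
    matches: list[Match] = []
    for i in range(len(a)):
        d1, j = float(dist[i, 0]), int(idx[i, 0])
        if d1 == 0 and j != i and i < len(b) and np.array_equal(
            a.descriptors[i], b.descriptors[i]
        ):
            j = i  # deterministic tie-break among exact duplicates
        if d1 > 0:
            if k == 2:
                d2 = float(dist[i, 1])
                if d2 > 0 and d1 / d2 >= cfg.ratio:
                    continue
            if cfg.mutual and int(back[j]) != i:
                continue
        elif cfg.mutual and float(np.linalg.norm(
            a.descriptors[int(back[j])] - b.descriptors[j]
        )) > 0:
            continue
        matches.append(
            Match(
                left_index=i,
                right_index=j,
                left_xy=(float(a.xy[i, 0]), float(a.xy[i, 1])),
                right_xy=(float(b.xy[j, 0]), float(b.xy[j, 1])),
                descriptor_distance=d1,
            )
        )
    return matches


def coherency_filter(
    matches: Sequence[Match],
    cfg: CoherencyConfig = CoherencyConfig(),
) -> list[Match]:
    """Keep matches that have at least one coherent neighboring match.

    A neighbor (c, d) of match (a, b) is coherent when ``|a - c| <= delta``
    and ``|b - d| <= epsilon`` (Euclidean, inclusive).  Exact via a KD tree
    over left endpoints; input order is preserved.
    """
    n = len(matches)
    if n == 0:
        return []
    left = np.array([m.left_xy for m in matches])
    right = np.array([m.right_xy for m in matches])
    tree = cKDTree(left)
    # small pad then exact re-check keeps the inclusive boundary robust
    neighbor_lists = tree.query_ball_point(left, cfg.delta_px * (1 + 1e-12))
    kept: list[Match] = []
    for i, neighbors in enumerate(neighbor_lists):
        ok = False
        for j in neighbors:
            if j == i:
                continue
            if (
                np.hypot(*(left[i] - left[j])) <= cfg.delta_px
                and np.hypot(*(right[i] - right[j])) <= cfg.epsilon_px
            ):
                ok = True
                break
        if ok:
            kept.append(matches[i])
    return kept


def count_matches_by_region(
    matches: Sequence[Match],
    template_regions: np.ndarray,
) -> dict[int | str, int]:
    """Count filtered matches per labeled template region.

    ``template_regions`` is an integer mask on the template image (0 =
    background).  A match is assigned to the region under its left endpoint
    (nearest pixel); endpoints on background or out of bounds count as
    ``"unassigned"``.
    """
    regions = np.asarray(template_regions)
    if regions.ndim != 2:
        raise InputError("region mask must be 2-D")
    region_ids = [int(r) for r in np.unique(regions) if r != 0]
    counts: dict[int | str, int] = {r: 0 for r in region_ids}
    counts["unassigned"] = 0
    h, w = regions.shape
    for m in matches:
        col = int(round(m.left_xy[0]))
        row = int(round(m.left_xy[1]))
        if 0 <= row < h and 0 <= col < w and regions[row, col] != 0:
            counts[int(regions[row, col])] += 1
        else:
            counts["unassigned"] += 1
    return counts


# ---------------------------------------------------------------------------
# I/O


MATCH_COLUMNS = [
    "left_index",
    "right_index",
    "left_x",
    "left_y",
    "right_x",
    "right_y",
    "distance",
]


def matches_to_frame(matches: Sequence[Match]) -> pd.DataFrame:
    rows = [
        (
            m.left_index,
            m.right_index,
            m.left_xy[0],
            m.left_xy[1],
            m.right_xy[0],
            m.right_xy[1],
            m.descriptor_distance,
        )
        for m in matches
    ]
    return pd.DataFrame(rows, columns=MATCH_COLUMNS)


def frame_to_matches(df: pd.DataFrame) -> list[Match]:
    return [
        Match(
            int(r.left_index),
            int(r.right_index),
            (float(r.left_x), float(r.left_y)),
            (float(r.right_x), float(r.right_y)),
            float(r.distance),
        )
        for r in df.itertuples(index=False)
    ]


def write_matches(matches: Sequence[Match], path) -> None:
    matches_to_frame(matches).to_csv(path, index=False)


def read_matches(path) -> list[Match]:
    return frame_to_matches(pd.read_csv(path))


def save_featureset(fs: FeatureSet, path) -> None:
    """Cache a FeatureSet as an .npz sidecar (keypoint table + descriptors)."""
    np.savez(
        path, image_id=fs.image_id, keypoints=fs.keypoints, descriptors=fs.descriptors
    )


def load_featureset(path) -> FeatureSet:
    data = np.load(path, allow_pickle=False)
    return FeatureSet(
        str(data["image_id"]), data["keypoints"], data["descriptors"]
    )
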