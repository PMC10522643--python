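"""Greedy template-atlas selection by cluster-weighted feature coverage.

Descriptors from the whole corpus are clustered; a feature's weight is the
number of not-yet-covered corpus features in its cluster, an image's weight
is the sum of its feature weights, and templates are picked greedily by
maximum current weight.  The selected atlas is then scored by actual
matching coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .barcode import CoherencyConfig, FeatureSet, MatchConfig, coherency_filter, match_features
from .errors import InputError


@dataclass
class ClusterModel:
    """K-means clustering of all corpus descriptors.

    ``assignment`` maps each corpus feature (corpus order: images in the
    given order, features within an image in their own order) to a cluster
    id; ``image_slices`` records each image's span in that flat order.
    """

    n_clusters: int
    assignment: np.ndarray
    cluster_sizes: np.ndarray
    image_ids: list[str]
    image_slices: dict[str, slice]
    seed: int

    def image_assignment(self, image_id: str) -> np.ndarray:
        return self.assignment[self.image_slices[image_id]]


@dataclass
class TemplateAtlas:
    """Ranked template ids with the greedy selection trace."""

    template_ids: list[str]
    selection_trace: list[tuple[str, float]] = field(default_factory=list)
    region_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.template_ids)) != len(self.template_ids):
            raise InputError("template ids must be unique")


def cluster_features(
    corpus: Sequence[FeatureSet],
    n_clusters: int,
    seed: int = 0,
) -> ClusterModel:
    """Cluster all corpus descriptors with seeded Lloyd k-means."""
    total = sum(len(fs) for fs in corpus)
    if n_clusters < 1 or n_clusters > total:
        raise InputError(
            f"n_clusters must lie in [1, {total}] for this corpus"
        )
    ids = [fs.image_id for fs in corpus]
    if len(set(ids)) != len(ids):
        raise InputError("corpus image ids must be unique")
    descriptors = np.vstack([fs.descriptors for fs in corpus])
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    assignment = km.fit_predict(descriptors)
    sizes = np.bincount(assignment, minlength=n_clusters)
    slices: dict[str, slice] = {}
    start = 0
    for fs in corpus:
        slices[fs.image_id] = slice(start, start + len(fs))
        start += len(fs)
    return ClusterModel(
        n_clusters=n_clusters,
        assignment=assignment,
        cluster_sizes=sizes,
        image_ids=ids,
        image_slices=slices,
        seed=seed,
    )


def default_n_clusters(feature_count: int) -> int:
    return max(1, min(2000, feature_count // 10))


def rank_templates_greedy(
    corpus: Sequence[FeatureSet],
    model: ClusterModel,
    n_select: int,
    decrement_mode: str = "cluster",
) -> TemplateAtlas:
    """Greedily rank templates by estimated count of newly covered features.

    At each step every image's weight is the sum of its feature weights,
    where a feature in cluster ``c`` weighs the number of not-yet-covered
    corpus features in ``c``.  The argmax image is picked (ties -> lowest
    image id) and the clusters it touches are marked covered.

    ``decrement_mode="feature"`` instead decrements each touched cluster by
    the picked image's per-cluster feature multiplicity.
    """
    if decrement_mode not in ("cluster", "feature"):
        raise InputError(f"unknown decrement mode {decrement_mode!r}")
    ids = [fs.image_id for fs in corpus]
    if set(ids) != set(model.image_ids):
        raise InputError("cluster model was built over a different corpus")
    if n_select > len(corpus):
        warnings.warn("n_select exceeds corpus size; truncating", stacklevel=2)
        n_select = len(corpus)

    remaining = model.cluster_sizes.astype(float).copy()
    per_image = {i: model.image_assignment(i) for i in ids}
    available = sorted(ids)
    picked: list[str] = []
    trace: list[tuple[str, float]] = []
    for _ in range(n_select):
        best_id, best_w = None, -np.inf
        for i in available:
            w = float(remaining[per_image[i]].sum())
            if w > best_w:
                best_id, best_w = i, w
        picked.append(best_id)
        trace.append((best_id, best_w))
        available.remove(best_id)
        touched = np.unique(per_image[best_id])
        if decrement_mode == "cluster":
            remaining[touched] = 0.0
        else:
            counts = np.bincount(per_image[best_id], minlength=len(remaining))
            remaining = np.maximum(remaining - counts, 0.0)
    return TemplateAtlas(template_ids=picked, selection_trace=trace)


def coverage_curve(
    atlas: TemplateAtlas,
    corpus: Sequence[FeatureSet],
    match_cfg: MatchConfig = MatchConfig(),
    coherency_cfg: CoherencyConfig = CoherencyConfig(),
) -> list[int]:
    """Cumulative count of distinct corpus features covered per atlas size.

    For each prefix of the atlas, every template is matched (then
    coherency-filtered) against every *other* corpus image; the count is the
    number of distinct (image, feature) pairs matched by at least one
    template so far.
    """
    by_id = {fs.image_id: fs for fs in corpus}
    missing = [t for t in atlas.template_ids if t not in by_id]
    if missing:
        raise InputError(f"atlas templates not in corpus: {missing}")
    covered: set[tuple[str, int]] = set()
    curve: list[int] = []
    for template_id in atlas.template_ids:
        template = by_id[template_id]
        for fs in corpus:
            if fs.image_id == template_id:
                continue
            matches = coherency_filter(
                match_features(template, fs, match_cfg), coherency_cfg
            )
            covered.update((fs.image_id, m.right_index) for m in matches)
        curve.append(len(covered))
    return curve
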