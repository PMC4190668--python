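"""Rule-based gel-panel assembly.

Panels are built in two stages. First, gel segments are grouped:
segments positive at the permissive (high-recall) operating point form a
graph whose edges connect segments at most ``adjacency_px`` apart with
no text segment between them; connected components of that graph are
kept only if they contain at least one segment positive at the strict
(high-precision) operating point — strict positives seed panels,
permissive positives merely extend them. Second, surrounding TEXT
segments are attributed to each group's hull region by the edge-distance
rule: nearest edge within ``near_px``, farthest corner within ``far_px``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .figure_model import (
    BoundingBox,
    FigureImage,
    PanelAnnotation,
    Segment,
    SegmentKind,
)
from .gel_classifier import GelClassifier

__all__ = [
    "GelPanel",
    "PanelConfig",
    "segment_distance",
    "point_to_boundary_distance",
    "max_corner_distance",
    "has_text_between",
    "group_segments_by_score",
    "group_gel_segments",
    "attribute_labels",
    "detect_panels",
]

DEFAULT_ADJACENCY_PX = 50.0
DEFAULT_LABEL_NEAR_PX = 30.0
DEFAULT_LABEL_FAR_PX = 150.0


@dataclass(frozen=True)
class PanelConfig:
    adjacency_px: float = DEFAULT_ADJACENCY_PX
    label_near_px: float = DEFAULT_LABEL_NEAR_PX
    label_far_px: float = DEFAULT_LABEL_FAR_PX


@dataclass
class GelPanel:
    """A detected panel: gel members, their hull region, attributed labels."""

    panel_id: str
    members: list[Segment]
    labels: list[Segment] = field(default_factory=list)

    @property
    def region(self) -> BoundingBox:
        return BoundingBox.hull_of(s.bbox for s in self.members)

    def to_annotation(self) -> PanelAnnotation:
        return PanelAnnotation(
            members=tuple(s.segment_id for s in self.members),
            labels=tuple(s.segment_id for s in self.labels),
        )


def segment_distance(a: BoundingBox, b: BoundingBox) -> float:
    """Euclidean distance between the closest points of two boxes.

    Zero when the boxes intersect or touch. With half-open boxes the
    coordinate gap ``b.x0 - a.x1`` is exactly the number of empty pixel
    columns between them.
    """
    dx = max(a.x0 - b.x1, b.x0 - a.x1, 0)
    dy = max(a.y0 - b.y1, b.y0 - a.y1, 0)
    return math.hypot(dx, dy)


def point_to_boundary_distance(px: float, py: float, box: BoundingBox) -> float:
    """Distance from a point to the boundary of a rectangle.

    For points outside this equals the distance to the rectangle; for
    points inside it is the distance to the nearest edge.
    """
    dx = max(box.x0 - px, px - box.x1, 0.0)
    dy = max(box.y0 - py, py - box.y1, 0.0)
    outside = math.hypot(dx, dy)
    if outside > 0.0:
        return outside
    return min(px - box.x0, box.x1 - px, py - box.y0, box.y1 - py)


def max_corner_distance(text_box: BoundingBox, region: BoundingBox) -> float:
    """Greatest distance from any corner of ``text_box`` to the region
    boundary — bounds the label's full extent."""
    corners = (
        (text_box.x0, text_box.y0),
        (text_box.x1, text_box.y0),
        (text_box.x0, text_box.y1),
        (text_box.x1, text_box.y1),
    )
    return max(point_to_boundary_distance(x, y, region) for x, y in corners)


def has_text_between(a: Segment, b: Segment, texts: Sequence[Segment]) -> bool:
    """True iff a TEXT box overlaps the corridor between ``a`` and ``b``.

    The corridor is the axis-aligned hull of the two boxes minus the
    boxes themselves; overlap must have positive area. This captures a
    caption row separating two stacked gels without letting far-away
    text break adjacency.
    """
    hull = a.bbox.hull(b.bbox)
    for t in texts:
        if t.kind is not SegmentKind.TEXT:
            continue
        in_hull = t.bbox.intersection_area(hull)
        if in_hull == 0:
            continue
        # Rectangle inclusion–exclusion: corridor overlap =
        # |T∩H| − |T∩A| − |T∩B| + |T∩A∩B| (A, B ⊆ H).
        in_a = t.bbox.intersection_area(a.bbox)
        in_b = t.bbox.intersection_area(b.bbox)
        in_ab = _triple_intersection_area(t.bbox, a.bbox, b.bbox)
        if in_hull - in_a - in_b + in_ab > 0:
            return True
    return False


def _triple_intersection_area(t: BoundingBox, a: BoundingBox, b: BoundingBox) -> int:
    x0 = max(t.x0, a.x0, b.x0)
    y0 = max(t.y0, a.y0, b.y0)
    x1 = min(t.x1, a.x1, b.x1)
    y1 = min(t.y1, a.y1, b.y1)
    return max(0, x1 - x0) * max(0, y1 - y0)


def group_segments_by_score(
    segments: Sequence[Segment],
    scores: Mapping[str, float],
    texts: Sequence[Segment],
    adjacency_px: float = DEFAULT_ADJACENCY_PX,
    high_recall_threshold: float = 0.15,
    high_precision_threshold: float = 0.60,
) -> list[list[Segment]]:
    """Connected-component grouping over pre-computed gel scores.

    The adjacency relation (distance <= adjacency_px AND no text
    between) is evaluated on the subgraph of high-recall-positive
    segments; components without a high-precision-positive member are
    discarded. Output order follows the first member's input position.
    """
    hr = [s for s in segments if scores.get(s.segment_id, 0.0) >= high_recall_threshold]
    n = len(hr)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if segment_distance(hr[i].bbox, hr[j].bbox) <= adjacency_px and not has_text_between(
                hr[i], hr[j], texts
            ):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    components: dict[int, list[Segment]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(hr[i])
    groups = [components[root] for root in sorted(components)]
    return [
        g
        for g in groups
        if any(scores[s.segment_id] >= high_precision_threshold for s in g)
    ]


def group_gel_segments(
    segments: Sequence[Segment],
    clf: GelClassifier,
    features: Mapping[str, np.ndarray],
    adjacency_px: float = DEFAULT_ADJACENCY_PX,
) -> list[list[Segment]]:
    """Score GRAPHIC segments with the classifier and group them.

    ``features`` maps segment_id to its length-39 feature array; all
    GRAPHIC segments must be covered. TEXT segments act only as
    adjacency blockers.
    """
    graphics = [s for s in segments if s.kind is SegmentKind.GRAPHIC]
    texts = [s for s in segments if s.kind is SegmentKind.TEXT]
    if not graphics:
        return []
    X = np.stack([np.asarray(features[s.segment_id]) for s in graphics])
    scores = dict(zip((s.segment_id for s in graphics), clf.score_many(X)))
    return group_segments_by_score(
        graphics,
        scores,
        texts,
        adjacency_px=adjacency_px,
        high_recall_threshold=clf.threshold("high_recall"),
        high_precision_threshold=clf.threshold("high_precision"),
    )


def attribute_labels(
    region: BoundingBox,
    texts: Sequence[Segment],
    near_px: float = DEFAULT_LABEL_NEAR_PX,
    far_px: float = DEFAULT_LABEL_FAR_PX,
) -> list[Segment]:
    """TEXT segments whose nearest edge is within ``near_px`` of the
    region and whose farthest corner is within ``far_px``."""
    out = []
    for t in texts:
        if t.kind is not SegmentKind.TEXT:
            continue
        if segment_distance(t.bbox, region) > near_px:
            continue
        if max_corner_distance(t.bbox, region) > far_px:
            continue
        out.append(t)
    return out


def detect_panels(
    fig: FigureImage,
    segments: Sequence[Segment],
    clf: GelClassifier,
    features: Mapping[str, np.ndarray],
    config: PanelConfig = PanelConfig(),
) -> list[GelPanel]:
    """Full panel detection: group gel segments, then attribute labels."""
    groups = group_gel_segments(
        segments, clf, features, adjacency_px=config.adjacency_px
    )
    texts = [s for s in segments if s.kind is SegmentKind.TEXT]
    panels = []
    for k, members in enumerate(groups):
        region = BoundingBox.hull_of(s.bbox for s in members)
        labels = attribute_labels(
            region, texts, near_px=config.label_near_px, far_px=config.label_far_px
        )
        panels.append(
            GelPanel(panel_id=f"{fig.image_id}:panel{k}", members=members, labels=labels)
        )
    return panels
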