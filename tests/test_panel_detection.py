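import math

import networkx as nx
import numpy as np
import pytest
from shapely.geometry import Point, box as shapely_box

from gelminer.figure_model import BoundingBox, SegmentKind
from gelminer.panel_detection import (
    GelPanel,
    attribute_labels,
    detect_panels,
    group_segments_by_score,
    has_text_between,
    max_corner_distance,
    segment_distance,
)
from .conftest import make_segment


def _shapely(b: BoundingBox):
    return shapely_box(b.x0, b.y0, b.x1, b.y1)


class TestSegmentDistance:
    def test_overlapping_boxes_zero(self):
        assert segment_distance(BoundingBox(0, 0, 10, 10),
                                BoundingBox(5, 5, 20, 20)) == 0.0

    def test_pure_horizontal_gap(self):
        assert segment_distance(BoundingBox(0, 0, 10, 10),
                                BoundingBox(20, 0, 30, 10)) == 10.0

    def test_diagonal_gap(self):
        assert segment_distance(BoundingBox(0, 0, 10, 10),
                                BoundingBox(13, 14, 20, 20)) == 5.0

    def test_touching_boxes_zero(self):
        assert segment_distance(BoundingBox(0, 0, 10, 10),
                                BoundingBox(10, 0, 20, 10)) == 0.0

    def test_symmetry(self):
        a, b = BoundingBox(3, 7, 9, 12), BoundingBox(40, 2, 55, 6)
        assert segment_distance(a, b) == segment_distance(b, a)

    def test_matches_shapely_on_random_boxes(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            def rand_box():
                x0, y0 = rng.integers(0, 200, size=2)
                return BoundingBox(int(x0), int(y0),
                                   int(x0) + int(rng.integers(1, 60)),
                                   int(y0) + int(rng.integers(1, 60)))
            a, b = rand_box(), rand_box()
            assert segment_distance(a, b) == pytest.approx(
                _shapely(a).distance(_shapely(b)), abs=1e-9)


class TestHasTextBetween:
    def test_no_text_segments(self):
        a = make_segment("a", (0, 0, 10, 10))
        b = make_segment("b", (30, 0, 40, 10))
        assert not has_text_between(a, b, [])

    def test_text_in_gap_detected(self):
        a = make_segment("a", (0, 0, 10, 10))
        b = make_segment("b", (30, 0, 40, 10))
        t = make_segment("t", (15, 2, 25, 8), kind=SegmentKind.TEXT, text="x")
        assert has_text_between(a, b, [t])

    def test_text_above_hull_ignored(self):
        a = make_segment("a", (0, 20, 10, 30))
        b = make_segment("b", (30, 20, 40, 30))
        t = make_segment("t", (12, 0, 28, 10), kind=SegmentKind.TEXT, text="x")
        assert not has_text_between(a, b, [t])

    def test_graphic_segments_do_not_block(self):
        a = make_segment("a", (0, 0, 10, 10))
        b = make_segment("b", (30, 0, 40, 10))
        g = make_segment("g", (15, 2, 25, 8))
        assert not has_text_between(a, b, [g])

    def test_text_inside_member_box_does_not_block(self):
        a = make_segment("a", (0, 0, 20, 20))
        b = make_segment("b", (40, 0, 60, 20))
        t = make_segment("t", (5, 5, 15, 15), kind=SegmentKind.TEXT, text="x")
        assert not has_text_between(a, b, [t])

    def test_matches_corridor_oracle_by_geometry(self):
        # Shapely oracle: corridor = hull minus the two boxes; blocking
        # iff text overlaps corridor with positive area.
        rng = np.random.default_rng(1)
        for _ in range(300):
            def rand_box(lo=0, hi=150, wmax=50):
                x0, y0 = rng.integers(lo, hi, size=2)
                return BoundingBox(int(x0), int(y0),
                                   int(x0) + int(rng.integers(1, wmax)),
                                   int(y0) + int(rng.integers(1, wmax)))
            a = make_segment("a", rand_box().as_tuple())
            b = make_segment("b", rand_box().as_tuple())
            t = make_segment("t", rand_box().as_tuple(),
                             kind=SegmentKind.TEXT, text="x")
            hull = _shapely(a.bbox.hull(b.bbox))
            corridor = hull.difference(_shapely(a.bbox).union(_shapely(b.bbox)))
            expected = _shapely(t.bbox).intersection(corridor).area > 1e-9
            assert has_text_between(a, b, [t]) == expected


class TestAttributeLabels:
    REGION = BoundingBox(100, 100, 300, 200)

    def test_near_and_compact_label_attributed(self):
        t = make_segment("t", (100, 70, 180, 80), kind=SegmentKind.TEXT, text="x")
        assert segment_distance(t.bbox, self.REGION) == 20.0
        assert max_corner_distance(t.bbox, self.REGION) <= 100
        assert attribute_labels(self.REGION, [t]) == [t]

    def test_nearest_edge_beyond_30_rejected(self):
        t = make_segment("t", (100, 50, 180, 60), kind=SegmentKind.TEXT, text="x")
        assert segment_distance(t.bbox, self.REGION) == 40.0
        assert attribute_labels(self.REGION, [t]) == []

    def test_long_bar_with_far_corner_rejected(self):
        # nearest 20 px, farthest corner > 150 px (very long text bar)
        t = make_segment("t", (100, 70, 460, 80), kind=SegmentKind.TEXT, text="x")
        assert segment_distance(t.bbox, self.REGION) == 20.0
        assert max_corner_distance(t.bbox, self.REGION) > 150
        assert attribute_labels(self.REGION, [t]) == []

    def test_graphic_segments_never_attributed(self):
        g = make_segment("g", (100, 70, 180, 80))
        assert attribute_labels(self.REGION, [g]) == []

    def test_matches_shapely_boundary_oracle(self):
        rng = np.random.default_rng(2)
        region = self.REGION
        ring = _shapely(region).exterior
        for _ in range(300):
            x0, y0 = rng.integers(0, 450, size=2)
            t = make_segment(
                "t", (int(x0), int(y0), int(x0) + int(rng.integers(1, 120)),
                      int(y0) + int(rng.integers(1, 30))),
                kind=SegmentKind.TEXT, text="x",
            )
            near = _shapely(t.bbox).distance(_shapely(region))
            corners = [(t.bbox.x0, t.bbox.y0), (t.bbox.x1, t.bbox.y0),
                       (t.bbox.x0, t.bbox.y1), (t.bbox.x1, t.bbox.y1)]
            far = max(ring.distance(Point(c)) for c in corners)
            expected = near <= 30 + 1e-6 and far <= 150 + 1e-6
            assert (attribute_labels(region, [t]) == [t]) == expected


def _scored(segs_with_scores):
    segments, scores = [], {}
    for sid, box, score in segs_with_scores:
        segments.append(make_segment(sid, box))
        scores[sid] = score
    return segments, scores


class TestGrouping:
    def test_lone_high_precision_seed(self):
        segments, scores = _scored([("a", (0, 0, 30, 30), 0.9)])
        groups = group_segments_by_score(segments, scores, [])
        assert [[s.segment_id for s in g] for g in groups] == [["a"]]

    def test_seed_plus_high_recall_neighbor_merged(self):
        segments, scores = _scored([
            ("hp", (0, 0, 30, 30), 0.9),
            ("hr", (70, 0, 100, 30), 0.2),  # 40 px apart
        ])
        groups = group_segments_by_score(segments, scores, [])
        assert [[s.segment_id for s in g] for g in groups] == [["hp", "hr"]]

    def test_text_between_splits_and_orphan_discarded(self):
        segments, scores = _scored([
            ("hp", (0, 0, 30, 30), 0.9),
            ("hr", (70, 0, 100, 30), 0.2),
        ])
        t = make_segment("t", (40, 5, 60, 25), kind=SegmentKind.TEXT, text="x")
        groups = group_segments_by_score(segments, scores, [t])
        assert [[s.segment_id for s in g] for g in groups] == [["hp"]]

    def test_no_seed_no_panels(self):
        segments, scores = _scored([
            ("hr1", (0, 0, 30, 30), 0.3),
            ("hr2", (40, 0, 70, 30), 0.3),  # 10 px apart
        ])
        assert group_segments_by_score(segments, scores, []) == []

    def test_beyond_adjacency_not_merged(self):
        segments, scores = _scored([
            ("hp", (0, 0, 30, 30), 0.9),
            ("hr", (81, 0, 111, 30), 0.2),  # 51 px apart
        ])
        groups = group_segments_by_score(segments, scores, [])
        assert [[s.segment_id for s in g] for g in groups] == [["hp"]]

    def test_transitive_chain_through_high_recall(self):
        segments, scores = _scored([
            ("hp", (0, 0, 30, 30), 0.9),
            ("m1", (40, 0, 70, 30), 0.2),
            ("m2", (80, 0, 110, 30), 0.2),
        ])
        groups = group_segments_by_score(segments, scores, [])
        assert [sorted(s.segment_id for s in g) for g in groups] == [
            ["hp", "m1", "m2"]
        ]

    def test_below_high_recall_never_included(self):
        segments, scores = _scored([
            ("hp", (0, 0, 30, 30), 0.9),
            ("junk", (40, 0, 70, 30), 0.1),
        ])
        groups = group_segments_by_score(segments, scores, [])
        assert [[s.segment_id for s in g] for g in groups] == [["hp"]]

    def test_monotone_in_adjacency_on_text_free_layouts(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            spec = []
            for i in range(8):
                x0, y0 = rng.integers(0, 300, size=2)
                spec.append((f"s{i}", (int(x0), int(y0),
                                       int(x0) + int(rng.integers(5, 50)),
                                       int(y0) + int(rng.integers(5, 50))),
                             float(rng.choice([0.0, 0.2, 0.9]))))
            segments, scores = _scored(spec)
            sizes = []
            for adj in (20.0, 50.0, 90.0):
                groups = group_segments_by_score(segments, scores, [],
                                                 adjacency_px=adj)
                sizes.append(max((len(g) for g in groups), default=0))
            assert sizes == sorted(sizes)


def brute_force_groups(segments, scores, texts, adjacency_px=50.0,
                       hr_t=0.15, hp_t=0.60):
    """Independent oracle: shapely geometry + networkx components."""
    hr = [s for s in segments if scores[s.segment_id] >= hr_t]
    g = nx.Graph()
    g.add_nodes_from(s.segment_id for s in hr)
    for i, a in enumerate(hr):
        for b in hr[i + 1:]:
            # Integer boxes: true distances near the threshold are either
            # exactly adjacency_px or differ by >> 1e-6, so the epsilon
            # only absorbs shapely's float rounding.
            if _shapely(a.bbox).distance(_shapely(b.bbox)) > adjacency_px + 1e-6:
                continue
            hull = _shapely(a.bbox.hull(b.bbox))
            corridor = hull.difference(
                _shapely(a.bbox).union(_shapely(b.bbox)))
            if any(
                t.kind is SegmentKind.TEXT
                and _shapely(t.bbox).intersection(corridor).area > 1e-9
                for t in texts
            ):
                continue
            g.add_edge(a.segment_id, b.segment_id)
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(c for c in comps
                  if any(scores[sid] >= hp_t for sid in c))


def random_layout(rng, n_boxes=None, canvas=400):
    n = int(n_boxes if n_boxes is not None else rng.integers(3, 16))
    segments, scores, texts = [], {}, []
    for i in range(n):
        x0, y0 = rng.integers(0, canvas - 60, size=2)
        seg = make_segment(f"g{i}", (int(x0), int(y0),
                                     int(x0) + int(rng.integers(10, 61)),
                                     int(y0) + int(rng.integers(10, 61))))
        segments.append(seg)
        scores[seg.segment_id] = float(rng.choice([0.0, 0.2, 0.4, 0.7, 1.0]))
    for j in range(int(rng.integers(0, 5))):
        x0, y0 = rng.integers(0, canvas - 80, size=2)
        texts.append(make_segment(f"t{j}", (int(x0), int(y0),
                                            int(x0) + int(rng.integers(10, 81)),
                                            int(y0) + int(rng.integers(5, 20))),
                                  kind=SegmentKind.TEXT, text="lbl"))
    return segments, scores, texts


class TestGroupingOracle:
    def test_matches_brute_force_on_random_layouts(self):
        rng = np.random.default_rng(1234)
        for _ in range(150):
            segments, scores, texts = random_layout(rng)
            got = sorted(
                sorted(s.segment_id for s in g)
                for g in group_segments_by_score(segments, scores, texts)
            )
            assert got == brute_force_groups(segments, scores, texts)

    def test_panels_disjoint_and_seeded(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            segments, scores, texts = random_layout(rng)
            groups = group_segments_by_score(segments, scores, texts)
            seen = set()
            for g in groups:
                ids = {s.segment_id for s in g}
                assert not ids & seen
                seen |= ids
                assert all(scores[sid] >= 0.15 for sid in ids)
                assert any(scores[sid] >= 0.60 for sid in ids)


class TestDetectPanels:
    def _perfect_clf(self, gel_box_set):
        class Perfect:
            def threshold(self, op):
                return {"high_recall": 0.15, "balanced": 0.3,
                        "high_precision": 0.6}[op]

            def score_many(self, X):
                # scores smuggled in as first feature
                return np.asarray(X)[:, 0]

        return Perfect()

    def test_no_high_precision_positives_gives_no_panels(self):
        from gelminer.figure_model import figure_from_array

        fig = figure_from_array("f", np.full((100, 100), 255))
        seg = make_segment("g", (10, 10, 40, 40))
        clf = self._perfect_clf(set())
        assert detect_panels(fig, [seg], clf, {"g": np.array([0.3])}) == []

    def test_two_separated_groups_give_two_panels(self):
        from gelminer.figure_model import figure_from_array

        fig = figure_from_array("f", np.full((400, 400), 255))
        segs = [
            make_segment("a1", (10, 10, 60, 40)),
            make_segment("a2", (70, 10, 120, 40)),
            make_segment("b1", (10, 300, 60, 330)),
            make_segment("b2", (70, 300, 120, 330)),
            make_segment("cap", (10, 150, 120, 165), kind=SegmentKind.TEXT,
                         text="caption"),
        ]
        feats = {sid: np.array([1.0]) for sid in ("a1", "a2", "b1", "b2")}
        panels = detect_panels(fig, segs, self._perfect_clf(None), feats)
        members = sorted(sorted(s.segment_id for s in p.members) for p in panels)
        assert members == [["a1", "a2"], ["b1", "b2"]]

    def test_grid_panel_with_column_and_row_labels(self):
        # 2x4 gel grid, 4 column labels above, 2 row labels left.
        from gelminer.figure_model import figure_from_array
        from gelminer.synthetic_figures import GeneratorConfig, generate_figure

        cfg = GeneratorConfig(seed=5, gel_panel_prob=1.0, second_panel_prob=0.0,
                              panel_rows=(2, 2), panel_cols=(4, 4),
                              n_distractors=(0, 0), decoy_label_prob=0.0)
        fig, ann = generate_figure(cfg, 0)
        assert len(ann.panels) == 1
        assert len(ann.panels[0].members) == 8
        assert len(ann.panels[0].labels) == 6
        feats = {
            s.segment_id: np.array([1.0 if s.is_gel else 0.0])
            for s in ann.segments if s.kind is SegmentKind.GRAPHIC
        }
        panels = detect_panels(fig, ann.segments, self._perfect_clf(None), feats)
        assert len(panels) == 1
        assert sorted(s.segment_id for s in panels[0].members) == sorted(
            ann.panels[0].members)
        assert sorted(s.segment_id for s in panels[0].labels) == sorted(
            ann.panels[0].labels)

    def test_panel_region_is_member_hull(self):
        p = GelPanel("p", members=[make_segment("a", (0, 0, 10, 10)),
                                   make_segment("b", (50, 20, 80, 60))])
        assert p.region == BoundingBox(0, 0, 80, 60)
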