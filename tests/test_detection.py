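"""Post-processing stages, reference detector, and the full pipeline."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovicount.detection import (
    EggCountResult,
    NullBackend,
    PipelineConfig,
    ReferenceBlobDetector,
    filter_confidence,
    filter_size,
    merge_detections,
    quantify_image,
)
from ovicount.evaluation import match_boxes
from ovicount.geometry import Box, iou
from ovicount.synthetic import EggTruth, SceneConfig, SceneTruth, generate_scene, render_scene

from conftest import random_int_box


def oracle_merge(boxes, threshold=0.5):
    """Independent transitive-closure merge: shapely IoU + networkx components,
    iterated until no pair of envelopes exceeds the threshold."""
    import networkx as nx
    from shapely import box as sbox

    def siou(a, b):
        pa, pb = sbox(a.x1, a.y1, a.x2, a.y2), sbox(b.x1, b.y1, b.x2, b.y2)
        inter = pa.intersection(pb).area
        return inter / pa.union(pb).area if inter else 0.0

    current = list(boxes)
    while True:
        g = nx.Graph()
        g.add_nodes_from(range(len(current)))
        for i in range(len(current)):
            for j in range(i + 1, len(current)):
                if siou(current[i], current[j]) > threshold:
                    g.add_edge(i, j)
        if g.number_of_edges() == 0:
            break
        current = [
            Box(
                min(current[i].x1 for i in comp),
                min(current[i].y1 for i in comp),
                max(current[i].x2 for i in comp),
                max(current[i].y2 for i in comp),
                confidence=max(current[i].confidence for i in comp),
            )
            for comp in nx.connected_components(g)
        ]
    return sorted(current, key=lambda b: (b.y1, b.x1, b.y2, b.x2))


class TestMergeDetections:
    def test_identical_boxes_keep_max_confidence(self):
        a = Box(0, 0, 10, 10, confidence=0.7)
        b = Box(0, 0, 10, 10, confidence=0.9)
        merged = merge_detections([a, b])
        assert merged == [Box(0, 0, 10, 10, confidence=0.9)]

    def test_iou_one_third_not_merged_at_default_threshold(self):
        out = merge_detections([Box(0, 0, 10, 10), Box(5, 0, 15, 10)], 0.5)
        assert len(out) == 2

    def test_chain_merges_transitively(self):
        # A~B and B~C overlap strongly, A~C barely: one envelope box
        a = Box(0, 0, 10, 10)
        b = Box(0, 2, 10, 12)
        c = Box(0, 4, 10, 14)
        assert iou([a, b]) > 0.5 and iou([b, c]) > 0.5 and iou([a, c]) < 0.5
        merged = merge_detections([a, b, c], 0.5)
        assert merged == [Box(0, 0, 10, 14)]
        assert merged == oracle_merge([a, b, c], 0.5)

    def test_empty_input(self):
        assert merge_detections([], 0.5) == []

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.integers(0, 6))
    def test_agrees_with_transitive_closure_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        boxes = [
            random_int_box(rng, canvas=48, max_side=24,
                           confidence=float(rng.uniform(0, 1)))
            for _ in range(n)
        ]
        assert merge_detections(boxes, 0.5) == oracle_merge(boxes, 0.5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_idempotent_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        boxes = [random_int_box(rng, canvas=48, max_side=24) for _ in range(6)]
        merged = merge_detections(boxes, 0.5)
        assert merge_detections(merged, 0.5) == merged
        perm = [boxes[i] for i in rng.permutation(len(boxes))]
        assert merge_detections(perm, 0.5) == merged


class TestSizeFilter:
    @pytest.mark.parametrize(
        "w, h, kept",
        [
            (19, 40, False),  # a side below 20 px: trichome/leaf-spot scale
            (45, 51, True),   # the average egg box
            (40, 91, False),  # a side above 90 px: nymph/smear scale
            (20, 90, True),   # boundaries are inclusive
        ],
    )
    def test_side_gates(self, w, h, kept):
        boxes = filter_size([Box(0, 0, w, h)], 20, 90)
        assert bool(boxes) is kept


class TestConfidenceFilter:
    def test_boundary_kept(self):
        boxes = [Box(0, 0, 10, 10, confidence=c) for c in (0.55, 0.60, 0.65)]
        assert len(filter_confidence(boxes, 0.6)) == 2
        assert len(filter_confidence(boxes, 0.0)) == 3
        assert len(filter_confidence(boxes, 1.0)) == 0

    def test_monotone_in_tau(self, rng):
        boxes = [Box(0, 0, 10, 10, confidence=float(c)) for c in rng.uniform(0, 1, 50)]
        sizes = [len(filter_confidence(boxes, t)) for t in np.linspace(0, 1, 21)]
        assert sizes == sorted(sizes, reverse=True)


def _single_egg_scene(cx, cy, height=1400, width=2800, a=30.0, b=13.0, angle=0.0):
    cfg = SceneConfig(height_px=height, width_px=width, n_eggs=0, seed=9)
    hw = math.sqrt((a * math.cos(angle)) ** 2 + (b * math.sin(angle)) ** 2)
    hh = math.sqrt((a * math.sin(angle)) ** 2 + (b * math.cos(angle)) ** 2)
    egg = EggTruth(center=(cx, cy), semi_major=a, semi_minor=b, angle_rad=angle,
                   maturity=0.8, box=Box(cx - hw, cy - hh, cx + hw, cy + hh))
    return SceneTruth(config=cfg, eggs=(egg,))


class TestReferenceDetector:
    def test_single_egg_high_confidence(self):
        img = render_scene(_single_egg_scene(700, 700, width=1400))
        dets = ReferenceBlobDetector().detect(img)
        assert len(dets) == 1
        assert dets[0].confidence > 0.8
        truth = _single_egg_scene(700, 700, width=1400).eggs[0].box
        assert iou([dets[0], truth]) > 0.5

    def test_thin_strand_scores_low(self):
        # egg-coloured but 3 px wide: sparse fill / extreme aspect ratio
        img = np.zeros((200, 200, 3), dtype=np.uint8)
        img[:, :] = (58, 105, 48)
        img[100:103, 60:140] = (140, 100, 60)
        dets = ReferenceBlobDetector().detect(img)
        assert all(d.confidence < 0.5 for d in dets)

    def test_empty_tile(self):
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        img[:, :] = (58, 105, 48)
        assert ReferenceBlobDetector().detect(img) == []

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError, match="RGB"):
            ReferenceBlobDetector().detect(np.zeros((64, 64), dtype=np.uint8))


class TestQuantifyImage:
    def test_blank_image_counts_zero(self):
        cfg = SceneConfig(height_px=1400, width_px=1400, n_eggs=0, seed=1)
        img = render_scene(generate_scene(cfg))
        assert quantify_image(img, ReferenceBlobDetector()).count == 0

    def test_well_separated_eggs_all_recovered(self):
        cfg = SceneConfig(height_px=1400, width_px=1400, n_eggs=10, seed=4)
        truth = generate_scene(cfg)
        res = quantify_image(render_scene(truth), ReferenceBlobDetector(), image_id="t")
        assert res.count == 10
        m = match_boxes(truth.boxes, res.final_boxes, 0.5)
        assert m.tp == 10 and m.fp == 0

    def test_straddling_egg_merged_once_with_padding(self):
        # egg centred on the core boundary at x = 1400 of a 1400x2800 scene
        truth = _single_egg_scene(1400.0, 700.0)
        img = render_scene(truth)
        res = quantify_image(img, ReferenceBlobDetector(), PipelineConfig())
        assert len(res.raw_boxes) == 2  # seen in both padded tiles
        assert res.count == 1

    def test_straddling_egg_double_counted_without_padding(self):
        truth = _single_egg_scene(1400.0, 700.0)
        img = render_scene(truth)
        res = quantify_image(
            img, ReferenceBlobDetector(), PipelineConfig(padding_px=0)
        )
        assert res.count == 2  # two disjoint half-views, nothing to merge

    def test_stage_monotonicity_and_final_predicates(self):
        cfg = SceneConfig(height_px=1400, width_px=2800, n_eggs=15, seed=6,
                          n_trichomes=6, n_specks=8, n_smears=1, n_honeydew_blobs=3)
        pipe = PipelineConfig()
        res = quantify_image(render_scene(generate_scene(cfg)),
                             ReferenceBlobDetector(), pipe)
        counts = [len(res.raw_boxes), len(res.merged_boxes),
                  len(res.size_filtered_boxes), len(res.final_boxes)]
        assert counts == sorted(counts, reverse=True)
        for b in res.final_boxes:
            assert pipe.min_side_px <= min(b.width, b.height)
            assert max(b.width, b.height) <= pipe.max_side_px
            assert b.confidence >= pipe.confidence_threshold
            assert 0 <= b.x1 < b.x2 <= 2800 and 0 <= b.y1 < b.y2 <= 1400

    def test_size_filter_removes_salted_specks_and_smears(self):
        # sub-20-px specks and >90-px smears are detected but size-filtered,
        # leaving exactly the true egg count
        cfg = SceneConfig(height_px=1400, width_px=2800, n_eggs=12, seed=17,
                          n_specks=15, n_smears=3)
        truth = generate_scene(cfg)
        res = quantify_image(render_scene(truth), ReferenceBlobDetector())
        assert len(res.merged_boxes) > 12  # the salt was really detected
        assert res.count == 12

    def test_backend_failure_names_tile(self):
        class Broken:
            name = "broken"

            def detect(self, tile):
                raise RuntimeError("boom")

        img = np.zeros((1400, 2800, 3), dtype=np.uint8)
        with pytest.raises(RuntimeError, match=r"broken.*\(0, 0\)"):
            quantify_image(img, Broken())

    def test_too_small_image_is_geometry_error(self):
        with pytest.raises(ValueError, match="too small"):
            quantify_image(np.zeros((100, 100, 3), dtype=np.uint8), NullBackend())


class TestConfigAndResult:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            PipelineConfig(merge_iou_threshold=0.0)
        with pytest.raises(ValueError):
            PipelineConfig(min_side_px=90, max_side_px=20)
        with pytest.raises(ValueError):
            PipelineConfig.from_dict({"min_size": 3})

    def test_result_stage_invariant_enforced(self):
        b = Box(0, 0, 30, 30, confidence=0.9)
        with pytest.raises(ValueError, match="non-increasing"):
            EggCountResult("x", (), (b,), (b,), (b,), PipelineConfig())
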