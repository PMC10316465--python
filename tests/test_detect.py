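"""Oracle detector, IoU matching (vs brute-force optimal), rate arithmetic."""

import itertools

import pytest
from scipy import stats

from patternpipe import coatsim as cs
from patternpipe import detect


def _det(image_id, bbox):
    return detect.Detection(image_id, bbox)


def _obj(bbox, **kw):
    defaults = dict(individual_id="i", pose="standing", side="right",
                    flank_visible_frac=1.0, rotation_deg=0.0, quality_score=3)
    defaults.update(kw)
    return cs.GroundTruthObject(bbox=bbox, **defaults)


class TestIoU:
    def test_identical_boxes(self):
        assert detect.iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0

    def test_disjoint_boxes(self):
        assert detect.iou((0, 0, 10, 10), (20, 20, 5, 5)) == 0.0

    def test_half_overlap_arithmetic(self):
        # overlap 5x10 = 50; union 100 + 100 - 50 = 150
        assert detect.iou((0, 0, 10, 10), (5, 0, 10, 10)) == pytest.approx(1 / 3)


class TestOracleDetect:
    def test_perfect_oracle_reproduces_boxes(self, small_catalog):
        for img in small_catalog:
            dets = detect.oracle_detect(img)
            assert [d.bbox for d in dets] == [o.bbox for o in img.objects]

    def test_total_miss(self, small_catalog):
        dets = detect.oracle_detect(small_catalog[0], miss_rate=1.0, seed=0)
        assert dets == []

    def test_miss_rate_binomially_plausible(self, individual):
        # 1000 objects at miss 0.174: emitted count in the binomial 99% band
        img = cs.render_photo(individual, seed=0)
        n, miss = 1000, 0.174
        emitted = sum(
            len(detect.oracle_detect(img, miss_rate=miss, seed=s))
            for s in range(n)
        )
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 1 - miss)
        assert lo <= emitted <= hi

    def test_deterministic_under_seed(self, small_catalog):
        a = detect.oracle_detect(small_catalog[0], miss_rate=0.3, false_rate=0.5,
                                 jitter_px=4, seed=11)
        b = detect.oracle_detect(small_catalog[0], miss_rate=0.3, false_rate=0.5,
                                 jitter_px=4, seed=11)
        assert [d.bbox for d in a] == [d.bbox for d in b]


class TestMatchDetections:
    def test_identical_all_tp(self):
        objs = [_obj((0, 0, 10, 10)), _obj((30, 30, 12, 8))]
        dets = [_det("im", o.bbox) for o in objs]
        a = detect.match_detections(dets, objs)
        assert len(a.pairs) == 2
        assert a.unmatched_detections == [] and a.unmatched_objects == []

    def test_disjoint_all_fp_fn(self):
        a = detect.match_detections([_det("im", (0, 0, 5, 5))],
                                    [_obj((50, 50, 5, 5))])
        assert a.pairs == []
        assert a.unmatched_detections == [0] and a.unmatched_objects == [0]

    def test_conservation(self):
        objs = [_obj((i * 20, 0, 15, 15)) for i in range(4)]
        dets = [_det("im", (i * 20 + 2, 1, 15, 15)) for i in range(3)]
        dets.append(_det("im", (200, 100, 10, 10)))  # spurious
        a = detect.match_detections(dets, objs)
        assert len(a.pairs) + len(a.unmatched_objects) == len(objs)
        assert len(a.pairs) + len(a.unmatched_detections) == len(dets)

    def test_greedy_agrees_with_bruteforce_optimal(self, rng):
        # exhaustive optimal one-to-one assignment over permutations
        for trial in range(30):
            nd, ng = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            dets = [_det("im", tuple(int(v) for v in (rng.integers(0, 80),
                    rng.integers(0, 80), rng.integers(5, 40), rng.integers(5, 40))))
                    for _ in range(nd)]
            objs = [_obj(tuple(int(v) for v in (rng.integers(0, 80),
                    rng.integers(0, 80), rng.integers(5, 40), rng.integers(5, 40))))
                    for _ in range(ng)]
            greedy = detect.match_detections(dets, objs, iou_threshold=0.5)
            r = min(nd, ng)
            best = 0
            for subset in itertools.combinations(range(nd), r):
                for perm in itertools.permutations(range(ng), r):
                    ious = [detect.iou(dets[i].bbox, objs[j].bbox)
                            for i, j in zip(subset, perm)]
                    best = max(best, sum(1 for v in ious if v >= 0.5))
            assert len(greedy.pairs) == best


class TestEvaluateDetector:
    def test_field_count_arithmetic(self):
        ev = detect.evaluation_from_counts(tp=2523, fp=129, fn=531,
                                           n_suitable=722, fn_suitable=5)
        r = ev.rounded()
        assert r["tp_rate"] == 0.951
        assert r["fp_rate"] == 0.049
        assert r["fn_rate"] == 0.174
        assert r["fn_rate_suitable"] == 0.007

    def test_rate_identities(self):
        ev = detect.evaluation_from_counts(tp=80, fp=20, fn=10)
        assert ev.tp_rate + ev.fp_rate == pytest.approx(1.0)
        assert ev.tp + ev.fp == ev.n_detections

    def test_empty_counts_flag_undefined(self):
        ev = detect.evaluation_from_counts(tp=0, fp=0, fn=0)
        assert ev.tp_rate is None
        assert "tp_rate" in ev.undefined_rates

    def test_perfect_oracle_rates(self, small_catalog):
        tp = fp = fn = 0
        for img in small_catalog:
            dets = detect.oracle_detect(img)
            a = detect.match_detections(dets, img.objects)
            ev = detect.evaluate_detector(a, img.objects)
            tp, fp, fn = tp + ev.tp, fp + ev.fp, fn + ev.fn
        total = detect.evaluation_from_counts(tp, fp, fn)
        assert total.tp_rate == 1.0 and total.fn_rate == 0.0


class TestCrop:
    def test_crop_dimensions(self, small_catalog):
        img = small_catalog[0]
        d = _det(img.image_id, (0, 0, 50, 100))
        c = detect.crop(img, d)
        assert c.pixels.shape[:2] == (100, 50)

    def test_padding_clipped_to_border(self, small_catalog):
        img = small_catalog[0]
        H, W = img.pixels.shape[:2]
        d = _det(img.image_id, (0, 0, 30, 30))
        c = detect.crop(img, d, padding_px=50)
        assert c.pixels.shape[:2] == (min(H, 80), min(W, 80))

    def test_zero_area_rejected(self, small_catalog):
        img = small_catalog[0]
        with pytest.raises(ValueError):
            detect.crop(img, _det(img.image_id, (5, 5, 0, 10)))

    def test_attributes_and_mask_attached(self, small_crops):
        for c in small_crops:
            assert c.attributes is not None
            assert c.mask is not None and c.mask.shape == c.pixels.shape[:2]

    def test_distinct_provenance(self, small_crops):
        assert len({c.crop_id for c in small_crops}) == len(small_crops)

    def test_detections_json_roundtrip(self, small_catalog, tmp_path):
        dets = detect.oracle_detect(small_catalog[0], false_rate=1.0, seed=3)
        path = tmp_path / "dets.json"
        detect.save_detections(dets, path)
        loaded = detect.load_detections(path)
        assert [d.bbox for d in loaded] == [d.bbox for d in dets]
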