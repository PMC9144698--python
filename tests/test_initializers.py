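import numpy as np
import pytest

from boxseg.domain import BoundingBox, box_union_mask
from boxseg.initializers import (
    InitializerConfig,
    circle_init,
    hybrid_init,
    initialize_targets,
    prediction_init,
)

from _oracles import circle_count_scalar


class TestCircleInit:
    def test_diameter_is_fraction_of_shorter_side(self):
        # 100x80 box, fraction 0.8 -> diameter 64 centred on the box
        box = BoundingBox(100, 90, 100, 80)
        cfg = InitializerConfig(circle_diameter_fraction=0.8)
        mask = circle_init(box, 200, 180, cfg)
        oracle = circle_count_scalar(100, 90, 64, 200, 180)
        assert mask.sum() == oracle
        ys, xs = np.nonzero(mask)
        assert xs.min() == 100 - 31 and xs.max() == 100 + 31

    def test_inscribed_circle_stays_inside_square_box(self):
        box = BoundingBox(20, 20, 16, 16)
        cfg = InitializerConfig(circle_diameter_fraction=1.0)
        mask = circle_init(box, 40, 40, cfg)
        union = box_union_mask([box], 40, 40)
        assert np.all(mask <= union)
        assert mask.sum() > 0

    def test_count_matches_brute_force_for_diameter_twenty(self):
        box = BoundingBox(15.5, 16.0, 25, 25)
        cfg = InitializerConfig(circle_diameter_fraction=0.8)  # diameter 20
        mask = circle_init(box, 32, 32, cfg)
        assert mask.sum() == circle_count_scalar(15.5, 16.0, 20, 32, 32)

    def test_rasterized_area_close_to_continuous_disc(self, rng):
        for _ in range(10):
            side = rng.uniform(20, 60)
            box = BoundingBox(50, 50, side, side * rng.uniform(1.0, 1.5))
            mask = circle_init(box, 100, 100, InitializerConfig())
            expected = np.pi * (0.4 * min(box.box_w, box.box_h)) ** 2
            assert 0.95 * expected <= mask.sum() <= 1.05 * expected

    def test_subpixel_diameter_raises(self):
        with pytest.raises(ValueError):
            circle_init(BoundingBox(5, 5, 1.0, 1.0), 10, 10, InitializerConfig())


class TestPredictionInit:
    def test_full_probability_clips_to_box(self):
        box = BoundingBox(8, 8, 6, 6)
        prob = np.ones((16, 16))
        mask = prediction_init(prob, [box], InitializerConfig())
        assert np.array_equal(mask, box_union_mask([box], 16, 16))

    def test_threshold_is_strict(self):
        prob = np.full((16, 16), 0.5)
        mask = prediction_init(prob, [BoundingBox(8, 8, 8, 8)], InitializerConfig())
        assert mask.sum() == 0

    def test_matches_threshold_then_clip_loop(self, rng):
        prob = rng.random((12, 12))
        box = BoundingBox(6, 5, 7, 9)
        mask = prediction_init(prob, [box], InitializerConfig())
        for y in range(12):
            for x in range(12):
                inside = (box.x_min <= x < box.x_max) and (box.y_min <= y < box.y_max)
                assert mask[y, x] == int(prob[y, x] > 0.5 and inside)


class TestHybridInit:
    def _prob_with_in_box_count(self, box, count, size=64):
        """Probability map with exactly `count` super-threshold pixels in the box."""
        prob = np.zeros((size, size))
        ys, xs = np.nonzero(box_union_mask([box], size, size))
        prob[ys[:count], xs[:count]] = 0.9
        return prob

    @pytest.mark.parametrize(
        "fraction,expect_circle", [(0.25, True), (0.30, False), (0.35, False)]
    )
    def test_area_rule_boundary_is_strict_less_than(self, fraction, expect_circle):
        box = BoundingBox(32, 32, 20, 20)  # area 400
        cfg = InitializerConfig(strategy="hybrid")
        prob = self._prob_with_in_box_count(box, int(fraction * 400))
        mask = hybrid_init(prob, [box], 64, 64, cfg)
        circle = circle_init(box, 64, 64, cfg)
        kept = prediction_init(prob, [box], cfg)
        assert np.array_equal(mask, circle if expect_circle else kept)

    def test_empty_prediction_falls_back_to_circle(self):
        box = BoundingBox(16, 16, 12, 12)
        cfg = InitializerConfig(strategy="hybrid")
        mask = hybrid_init(np.zeros((32, 32)), [box], 32, 32, cfg)
        assert np.array_equal(mask, circle_init(box, 32, 32, cfg))

    def test_limits_recover_the_pure_strategies(self):
        box = BoundingBox(16, 16, 10, 14)
        cfg = InitializerConfig(strategy="hybrid")
        ones = np.ones((32, 32))
        assert np.array_equal(hybrid_init(ones, [box], 32, 32, cfg),
                              prediction_init(ones, [box], cfg))
        zeros = np.zeros((32, 32))
        assert np.array_equal(hybrid_init(zeros, [box], 32, 32, cfg),
                              circle_init(box, 32, 32, cfg))

    def test_multi_box_decides_per_box(self):
        good = BoundingBox(10, 10, 10, 10)
        bad = BoundingBox(40, 40, 10, 10)
        prob = np.zeros((64, 64))
        prob[5:15, 5:15] = 0.9  # covers `good` fully, `bad` not at all
        cfg = InitializerConfig(strategy="hybrid")
        mask = hybrid_init(prob, [good, bad], 64, 64, cfg)
        expected = prediction_init(prob, [good], cfg) | circle_init(bad, 64, 64, cfg)
        assert np.array_equal(mask, expected)


class TestPositivesStayInBoxes:
    @pytest.mark.parametrize("strategy", ["circle", "prediction", "hybrid"])
    def test_every_strategy_respects_the_boxes(self, strategy, rng):
        for _ in range(8):
            w = h = 48
            box = BoundingBox(rng.uniform(12, 36), rng.uniform(12, 36),
                              rng.uniform(6, 20), rng.uniform(6, 20))
            prob = rng.random((h, w))
            cfg = InitializerConfig(strategy=strategy)
            if strategy == "circle":
                mask = circle_init(box, w, h, cfg)
            elif strategy == "prediction":
                mask = prediction_init(prob, [box], cfg)
            else:
                mask = hybrid_init(prob, [box], w, h, cfg)
            union = box_union_mask([box], w, h)
            assert not np.any((mask == 1) & (union == 0))


class TestInitializeTargets:
    def test_fixed_images_keep_their_masks_and_hybrid_needs_predictor(self, smoke_bench):
        from boxseg.synthetic import apply_mix_labels

        split = apply_mix_labels(smoke_bench.split, 0.5, seed=0)
        fixed_before = {
            im.image_id: im.target.copy() for im in split.train if im.fixed_target
        }
        log = initialize_targets(split.train, InitializerConfig(strategy="circle"))
        for im in split.train:
            if im.image_id in fixed_before:
                assert np.array_equal(im.target, fixed_before[im.image_id])
        sources = {e["image_id"]: e["source"] for e in log}
        assert all(sources[i] == "fixed" for i in fixed_before)
        with pytest.raises(ValueError):
            initialize_targets(split.train, InitializerConfig(strategy="hybrid"))
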