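import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duospot.detect import (DetectionParams, count_double_spots, detect_frame,
                            estimate_background, find_spots, match_to_truth,
                            pair_spots, pairs_to_mask)
from duospot.simulate import _stamp_gaussian

from conftest import truth_pair_midpoints


def brute_force_max_matching_count(spots, params):
    """Independent oracle: enumerate all pairings, return the maximum number
    of disjoint valid pairs."""
    spots = np.asarray(spots, dtype=float)
    n = len(spots)
    valid = []
    for i, j in itertools.combinations(range(n), 2):
        dy, dx = spots[j, 0] - spots[i, 0], spots[j, 1] - spots[i, 1]
        sep = np.hypot(dy, dx)
        if abs(sep - params.expected_separation_px) > params.separation_tol_px:
            continue
        ang = np.degrees(np.arctan2(dy, dx)) % 180.0
        d = abs(ang - params.axis_angle_deg % 180.0) % 180.0
        if min(d, 180.0 - d) > params.angle_tol_deg:
            continue
        valid.append((i, j))
    best = 0
    for r in range(len(valid), 0, -1):
        for combo in itertools.combinations(valid, r):
            used = [k for ij in combo for k in ij]
            if len(used) == len(set(used)):
                best = r
                break
        if best:
            break
    return best


def synthetic_frame(spot_positions, photons=2000.0, background=100.0,
                    shape=(128, 128), sigma=1.3, rng=None):
    img = np.full(shape, background, dtype=float)
    for r, c in spot_positions:
        _stamp_gaussian(img, r, c, photons, sigma)
    if rng is not None:
        img = rng.poisson(img).astype(float)
    return img


class TestBackground:
    def test_constant_frame_recovered(self):
        bg = estimate_background(np.full((128, 128), 77.0))
        assert np.allclose(bg, 77.0)

    def test_spot_does_not_bias_background(self):
        img = synthetic_frame([(64.0, 64.0)], photons=5000)
        bg = estimate_background(img)
        assert abs(bg[64, 64] - 100.0) / 100.0 < 0.02

    def test_gradient_tracked_and_snr_improves(self):
        grad = np.linspace(50, 200, 128)[:, None] * np.ones((1, 128))
        img = grad.copy()
        _stamp_gaussian(img, 64.2, 80.7, 3000, 1.3)
        bg = estimate_background(img)
        inner = np.s_[16:-16, 16:-16]  # away from filter boundary effects
        # a bright spot on a ramp shifts the local median by at most a few
        # counts (order-statistic shift); the 150-count ramp is tracked
        assert np.abs((bg - grad)[inner]).max() < 6.0
        residual = img - bg
        assert residual[64, 81] > 10 * np.abs(residual[inner]).std()

    def test_non_2d_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_background(np.zeros((4, 4, 4)))


class TestFindSpots:
    def test_single_spot_localized_subpixel(self):
        img = synthetic_frame([(100.0, 64.0)], shape=(128, 128))
        spots = find_spots(img - 100.0)
        assert len(spots) == 1
        assert abs(spots[0, 0] - 100.0) < 0.3
        assert abs(spots[0, 1] - 64.0) < 0.3

    def test_pure_noise_rarely_triggers(self):
        rng = np.random.default_rng(0)
        n_fp = 0
        for _ in range(20):
            frame = rng.poisson(100, (128, 128)).astype(float)
            n_fp += len(find_spots(frame - 100.0))
        assert n_fp <= 1  # expected << 1 false positive per frame at 5 sigma

    def test_close_pair_resolved(self):
        img = synthetic_frame([(64.0, 60.0), (64.0, 66.5)])
        spots = find_spots(img - 100.0)
        assert len(spots) == 2

    def test_edge_spots_discarded(self):
        img = synthetic_frame([(2.0, 64.0), (64.0, 64.0)])
        spots = find_spots(img - 100.0)
        assert len(spots) == 1


class TestPairSpots:
    def test_matching_separation_gives_one_pair(self):
        spots = np.array([[50.0, 50.0, 100.0], [50.0, 56.5, 90.0]])
        pairs, singles = pair_spots(spots)
        assert len(pairs) == 1 and len(singles) == 0
        assert pairs[0].separation_px == pytest.approx(6.5)

    def test_far_separation_gives_no_pair(self):
        spots = np.array([[50.0, 50.0, 100.0], [50.0, 50.0 + 6.5 + 15, 90.0]])
        pairs, singles = pair_spots(spots)
        assert len(pairs) == 0 and len(singles) == 2

    def test_off_axis_pair_rejected(self):
        spots = np.array([[50.0, 50.0, 100.0], [56.5, 50.0, 90.0]])  # vertical
        pairs, _ = pair_spots(spots)
        assert len(pairs) == 0

    def test_chain_conflict_resolved_to_maximum_matching(self):
        # A-B-C-D chain where the middle pair is brightest: max matching is 2
        spots = np.array([[50.0, 10.0, 100.0], [50.0, 16.5, 500.0],
                          [50.0, 23.0, 500.0], [50.0, 29.5, 100.0]])
        pairs, _ = pair_spots(spots)
        assert len(pairs) == 2

    @given(st.integers(min_value=0, max_value=10_000),
           st.integers(min_value=2, max_value=6))
    @settings(max_examples=60, deadline=None)
    def test_pairing_count_equals_bruteforce_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        params = DetectionParams()
        # cluster positions around a few anchors so valid pairs are common
        spots = np.column_stack([
            rng.uniform(20, 60, n),
            rng.uniform(20, 60, n),
            rng.uniform(50, 500, n),
        ])
        pairs, _ = pair_spots(spots, params)
        assert len(pairs) == brute_force_max_matching_count(spots, params)

    def test_pairing_deterministic(self):
        rng = np.random.default_rng(5)
        spots = np.column_stack([rng.uniform(20, 100, 12),
                                 rng.uniform(20, 100, 12),
                                 rng.uniform(50, 500, 12)])
        p1, _ = pair_spots(spots)
        p2, _ = pair_spots(spots)
        assert [(p.row1, p.col1) for p in p1] == [(p.row1, p.col1) for p in p2]


class TestCountDoubleSpots:
    def test_blank_stack_counts_zero(self):
        rng = np.random.default_rng(1)
        frames = rng.poisson(100, (5, 128, 128)).astype(np.uint16)
        counts, _ = count_double_spots(frames)
        assert counts.sum() <= 1

    def test_counts_recover_truth_on_clean_stack(self, cluster_stack):
        stack, truth = cluster_stack
        from duospot.simulate import true_pair_counts
        counts, _ = count_double_spots(stack)
        true = true_pair_counts(truth, stack.n_frames)
        assert counts.sum() == pytest.approx(true.sum(), rel=0.05)

    def test_determinism_same_stack_twice(self, cluster_stack):
        stack, _ = cluster_stack
        c1, _ = count_double_spots(stack.frames[:3])
        c2, _ = count_double_spots(stack.frames[:3])
        assert np.array_equal(c1, c2)

    def test_mixed_shapes_rejected(self):
        with pytest.raises(ValueError):
            count_double_spots(
                np.array([np.zeros((8, 8)), np.zeros((6, 6))], dtype=object))

    def test_measured_separation_close_to_configured(self, cluster_stack):
        stack, _ = cluster_stack
        _, results = count_double_spots(stack)
        seps = [p.separation_px for r in results for p in r.pairs]
        assert len(seps) > 50
        assert np.mean(seps) == pytest.approx(6.5, abs=0.3)

    def test_mask_components_equal_pair_count(self, cluster_stack):
        stack, _ = cluster_stack
        res = detect_frame(stack.frames[0], DetectionParams(), with_mask=True)
        from duospot.unet import mask_to_count
        assert mask_to_count(res.mask, min_area_px=1) == res.count


class TestMatchToTruth:
    def test_perfect_detections(self):
        pts = np.array([[10.0, 10.0], [40.0, 40.0]])
        m = match_to_truth(pts, pts, radius_px=2)
        assert m["precision"] == 1.0 and m["recall"] == 1.0

    def test_empty_detections_convention(self):
        m = match_to_truth(np.empty((0, 2)), np.array([[5.0, 5.0]]))
        assert m["recall"] == 0.0
        assert m["precision"] == 1.0 and not m["precision_defined"]

    def test_one_planted_false_positive(self):
        truth = np.column_stack([np.arange(9) * 10.0 + 5, np.full(9, 50.0)])
        det = np.vstack([truth, [[200.0, 200.0]]])
        m = match_to_truth(det, truth, radius_px=2)
        assert m["precision"] == pytest.approx(0.9)
        assert m["recall"] == 1.0

    def test_saturation_undercounts_at_high_density(self, small_geom,
                                                    lp_filter, small_slab):
        # recovered/true ratio falls as pair density grows past overlap
        from duospot.simulate import cluster_spec, simulate_stack, \
            true_pair_counts
        from conftest import conc_for_mean
        spec = cluster_spec(lp_filter)
        ratios = []
        for mean in (5.0, 60.0, 200.0):
            c = conc_for_mean(mean, small_slab.volume_fL)
            stack, truth = simulate_stack([(spec, c)], 4, small_slab,
                                          small_geom, lp_filter, seed=13)
            counts, _ = count_double_spots(stack)
            ratios.append(counts.sum() / true_pair_counts(truth, 4).sum())
        assert ratios[0] > ratios[1] > ratios[2]


class TestPairsToMask:
    def test_pair_disks_form_one_component(self):
        from duospot.detect import SpotPair
        from duospot.unet import mask_to_count
        pair = SpotPair(50.0, 50.0, 50.0, 56.5, 100.0, 90.0)
        mask = pairs_to_mask([pair], (100, 100))
        assert mask_to_count(mask, min_area_px=1) == 1
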