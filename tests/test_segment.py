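import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proteocast import (
    SegmentationConfig,
    flag_idr_segments,
    fpop_segment,
    hall_variance,
    optimal_partition_reference,
    plddt_weights,
    score_segments,
    segment_profile,
)
from proteocast.errors import SegmentationInputError
from proteocast.landscape import SensitivityProfile
from proteocast.segment import Segmentation
from proteocast.simulate import planted_profile


class TestPlddtWeights:
    def test_high_confidence_down_weighted(self):
        assert plddt_weights(np.array([80.0, 60.0]), 2).tolist() == [0.1, 1.0]

    def test_cutoff_is_strict(self):
        assert plddt_weights(np.array([70.0]), 1).tolist() == [1.0]

    def test_no_structure_all_ones(self):
        assert plddt_weights(None, 5).tolist() == [1.0] * 5

    def test_nan_positions_get_weight_one(self):
        w = plddt_weights(np.array([90.0, np.nan]), 2)
        assert w.tolist() == [0.1, 1.0]

    def test_length_mismatch(self):
        with pytest.raises(SegmentationInputError):
            plddt_weights(np.array([80.0]), 2)


class TestHallVariance:
    def test_constant_signal_is_zero(self):
        est = hall_variance(np.full(100, 3.7))
        assert est.sigma2 == pytest.approx(0.0, abs=1e-300)

    def test_iid_gaussian_noise(self):
        """sigma2 within 15% of truth in >= 90% of 100 seeds at n=500."""
        hits = sum(
            abs(hall_variance(
                np.random.default_rng(s).normal(0, 1, 500)
            ).sigma2 - 1.0) < 0.15
            for s in range(100)
        )
        assert hits >= 90

    def test_robust_to_mean_shifts(self):
        """Three planted jumps barely perturb the estimate (within 20%)."""
        hits = 0
        for s in range(100):
            y = planted_profile(
                500, [125, 250, 375, 500], [0.0, 4.0, 0.0, 4.0], 1.0, seed=s
            )
            hits += abs(hall_variance(y).sigma2 - 1.0) < 0.20
        assert hits >= 90

    def test_too_short(self):
        with pytest.raises(SegmentationInputError):
            hall_variance(np.array([1.0, 2.0, 3.0]))


class TestFpop:
    def test_constant_vector_one_segment(self):
        seg = fpop_segment(np.full(30, 2.5), np.ones(30), penalty=1.0)
        assert seg.changepoints == [30]
        assert seg.segment_means[0] == pytest.approx(2.5)

    def test_clean_step_recovered(self):
        y = np.concatenate([np.zeros(20), np.full(20, 5.0)])
        seg = fpop_segment(y, np.ones(40), penalty=2.0)
        assert seg.changepoints == [20, 40]
        ends, cost = optimal_partition_reference(y, np.ones(40), 2.0)
        assert ends == [20, 40]
        assert seg.total_cost == pytest.approx(cost)

    def test_zero_penalty_singletons(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=25)
        seg = fpop_segment(y, np.ones(25), penalty=0.0)
        assert seg.changepoints == list(range(1, 26))
        assert seg.total_cost == pytest.approx(0.0, abs=1e-12)

    def test_huge_penalty_single_segment(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=50)
        penalty = 50 * (y.max() - y.min()) ** 2
        seg = fpop_segment(y, np.ones(50), penalty)
        assert seg.changepoints == [50]

    def test_matches_exhaustive_dp_on_random_instances(self):
        """Changepoints and penalised cost equal the O(n^2) optimal
        partitioning DP on random weighted signals."""
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(5, 120))
            means = np.repeat(
                rng.normal(scale=3, size=4), [n // 4] * 3 + [n - 3 * (n // 4)]
            )
            y = means + rng.normal(size=n)
            w = rng.choice([0.1, 1.0], size=n)
            penalty = float(rng.uniform(0.1, 12.0))
            seg = fpop_segment(y, w, penalty)
            ends, cost = optimal_partition_reference(y, w, penalty)
            assert seg.changepoints == ends
            assert seg.total_cost == pytest.approx(cost, rel=1e-9)

    def test_total_cost_identity(self):
        """total_cost recomputes exactly as weighted SSE + (K-1) * penalty."""
        rng = np.random.default_rng(3)
        y = rng.normal(size=80) + np.repeat([0, 4], 40)
        w = rng.choice([0.1, 1.0], size=80)
        seg = fpop_segment(y, w, 3.0)
        sse = 0.0
        start = 0
        for end, mu in zip(seg.changepoints, seg.segment_means):
            ys, ws = y[start:end], w[start:end]
            assert mu == pytest.approx(float((ws * ys).sum() / ws.sum()))
            sse += float((ws * (ys - mu) ** 2).sum())
            start = end
        assert seg.total_cost == pytest.approx(
            sse + (seg.n_segments - 1) * 3.0, rel=1e-12
        )

    def test_segment_count_monotone_in_penalty(self):
        rng = np.random.default_rng(9)
        y = planted_profile(150, [50, 100, 150], [0, 3, 0], 1.0, seed=5)
        w = rng.choice([0.1, 1.0], size=150)
        counts = [
            fpop_segment(y, w, p).n_segments
            for p in np.linspace(0.0, 60.0, 20)
        ]
        assert counts == sorted(counts, reverse=True)

    @given(shift=st.floats(-10, 10), seed=st.integers(0, 50))
    @settings(max_examples=25)
    def test_shift_equivariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=40) + np.repeat([0, 3], 20)
        w = rng.choice([0.1, 1.0], size=40)
        a = fpop_segment(y, w, 2.0)
        b = fpop_segment(y + shift, w, 2.0)
        assert a.changepoints == b.changepoints
        assert np.allclose(a.segment_means + shift, b.segment_means)

    def test_sign_flip_duality(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=60) + np.repeat([0, 2, -1], 20)
        w = rng.choice([0.1, 1.0], size=60)
        assert (
            fpop_segment(y, w, 2.0).changepoints
            == fpop_segment(-y, w, 2.0).changepoints
        )

    def test_scale_equivariance(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=50) + np.repeat([0, 3], 25)
        w = np.ones(50)
        c = 2.5
        a = fpop_segment(y, w, 4.0)
        b = fpop_segment(c * y, w, c * c * 4.0)
        assert a.changepoints == b.changepoints

    @pytest.mark.parametrize(
        "y,w,penalty",
        [
            (np.array([1.0, np.nan]), np.ones(2), 1.0),
            (np.array([1.0, 2.0]), np.array([1.0, 0.0]), 1.0),
            (np.array([1.0, 2.0]), np.ones(2), -1.0),
        ],
    )
    def test_invalid_inputs(self, y, w, penalty):
        with pytest.raises(SegmentationInputError):
            fpop_segment(y, w, penalty)


class TestSegmentProfile:
    def test_planted_changepoints_recovered(self):
        """All four planted changepoints found within +-2 positions in a
        quick 20-seed version of the recovery simulation."""
        hits = 0
        for seed in range(20):
            y = planted_profile(
                300, [60, 120, 180, 240, 300],
                [0.0, 1.75, 0.0, 1.75, 0.0], 0.5, seed=seed,
            )
            plddt = np.array([90.0] * 150 + [40.0] * 150)
            seg = segment_profile(SensitivityProfile(values=y), plddt)
            if all(
                any(abs(cp - t) <= 2 for cp in seg.changepoints)
                for t in (60, 120, 180, 240)
            ):
                hits += 1
        assert hits >= 19

    def test_alpha_controls_granularity(self):
        y = planted_profile(
            300, [60, 120, 180, 240, 300], [0, 1.75, 0, 1.75, 0], 0.5, seed=0
        )
        prof = SensitivityProfile(values=y)
        fine = segment_profile(prof, None, SegmentationConfig(alpha=1.4))
        coarse = segment_profile(prof, None, SegmentationConfig(alpha=100.0))
        assert coarse.n_segments < fine.n_segments

    def test_down_weighting_suppresses_segments(self):
        """High-pLDDT (down-weighted) runs never yield more segments than
        the same signal treated as disordered."""
        for seed in range(10):
            y = planted_profile(200, [200], [0.0], 1.0, seed=seed)
            prof = SensitivityProfile(values=y)
            hi = segment_profile(prof, np.full(200, 95.0))
            lo = segment_profile(prof, np.full(200, 40.0))
            assert hi.n_segments <= lo.n_segments

    def test_sigma2_override(self):
        y = planted_profile(100, [100], [0.0], 1.0, seed=0)
        seg = segment_profile(
            SensitivityProfile(values=y), None,
            SegmentationConfig(sigma2_override=2.0),
        )
        assert seg.variance.method == "override"
        assert seg.penalty == pytest.approx(1.4 * 2.0 * np.log(100))


def make_seg(means):
    k = len(means)
    return Segmentation(
        changepoints=list(range(10, 10 * k + 1, 10)),
        segment_means=np.asarray(means, dtype=float),
        penalty=1.0,
        total_cost=0.0,
        weights_used=np.ones(10 * k),
    )


class TestScoreSegments:
    def test_valley_scores_two(self):
        seg = score_segments(make_seg([-1.0, -5.0, -1.0]))
        assert seg.segment_scores[1] == 2
        # terminal segments compare to one neighbour only
        assert seg.segment_scores[0] in (0, 1)

    def test_terminal_rule(self):
        seg = score_segments(make_seg([-5.0, -1.0]))
        assert seg.segment_scores.tolist() == [1, 0]

    def test_monotone_means(self):
        seg = score_segments(make_seg([-3.0, -2.0, -1.0]))
        assert seg.segment_scores.tolist() == [1, 1, 0]

    def test_single_segment_scores_zero(self):
        seg = score_segments(make_seg([-2.0]))
        assert seg.segment_scores.tolist() == [0]

    def test_ties_are_not_elevated(self):
        seg = score_segments(make_seg([-1.0, -1.0, -1.0]))
        assert seg.segment_scores.tolist() == [0, 0, 0]


class TestIdrFlags:
    def test_disordered_scoring_segment_highlighted(self):
        seg = score_segments(make_seg([-1.0, -5.0, -1.0]))
        flag_idr_segments(seg, np.full(30, 40.0))
        assert seg.in_idr.tolist() == [True, True, True]

    def test_ordered_segment_not_flagged(self):
        seg = score_segments(make_seg([-1.0, -5.0, -1.0]))
        flag_idr_segments(seg, np.full(30, 90.0))
        assert seg.in_idr.tolist() == [False, False, False]

    def test_no_structure_everything_is_idr(self):
        seg = score_segments(make_seg([-1.0, -5.0, -1.0]))
        flag_idr_segments(seg, None)
        assert seg.in_idr.all()

    def test_majority_rule(self):
        seg = score_segments(make_seg([-1.0, -5.0]))
        plddt = np.array([40.0] * 6 + [90.0] * 4 + [90.0] * 10)
        flag_idr_segments(seg, plddt)
        assert seg.in_idr.tolist() == [True, False]
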