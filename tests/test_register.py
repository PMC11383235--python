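import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from replicascan.register import (
    AlignmentError,
    MatchConfig,
    estimate_affine,
    apply_affine,
    estimate_translation,
    match_patterns,
    matching_percentages,
)
from replicascan.synth import SyntheticScanConfig, generate_ground_truth, simulate_scan

from conftest import brute_force_match, make_set


class TestEstimateTranslation:
    def test_identical_patterns_give_zero_shift(self, rng):
        xy = rng.uniform(0, 100, size=(200, 2))
        A = make_set(xy, "A")
        B = make_set(xy, "B")
        dx, dy = estimate_translation(A, B)
        assert abs(dx) < 1e-9 and abs(dy) < 1e-9

    def test_recovers_exact_translation(self, rng):
        xy = rng.uniform(0, 100, size=(300, 2))
        A = make_set(xy, "A")
        B = make_set(xy + [0.5, -0.3], "B")
        dx, dy = estimate_translation(A, B)
        # shift applied to B restores A's frame
        assert dx == pytest.approx(-0.5, abs=1e-9)
        assert dy == pytest.approx(0.3, abs=1e-9)

    def test_recovers_translation_under_jitter(self, rng):
        xy = rng.uniform(0, 200, size=(500, 2))
        jitter = rng.normal(0, 0.1, size=(500, 2))
        A = make_set(xy, "A")
        B = make_set(xy + [1.0, 1.0] + jitter, "B")
        dx, dy = estimate_translation(A, B)
        assert dx == pytest.approx(-1.0, abs=0.05)
        assert dy == pytest.approx(-1.0, abs=0.05)

    def test_distant_patterns_raise_alignment_error(self):
        A = make_set([[0.0, 0.0], [1.0, 0.0]], "A")
        B = make_set([[500.0, 500.0], [501.0, 500.0]], "B")
        with pytest.raises(AlignmentError):
            estimate_translation(A, B)

    def test_empty_set_rejected(self):
        A = make_set(np.empty((0, 2)), "A")
        B = make_set([[1.0, 1.0]], "B")
        with pytest.raises(AlignmentError):
            estimate_translation(A, B)


class TestEstimateAffine:
    def test_identity(self, rng):
        pts = rng.uniform(0, 50, size=(20, 2))
        M, t = estimate_affine(pts, pts)
        assert np.allclose(M, np.eye(2), atol=1e-10)
        assert np.allclose(t, 0, atol=1e-9)

    def test_recovers_rotation_scale_shift(self, rng):
        theta = np.deg2rad(5.0)
        R = 1.01 * np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        shift = np.array([3.0, -2.0])
        pb = rng.uniform(0, 100, size=(50, 2))
        pa = pb @ R.T + shift
        M, t = estimate_affine(pb, pa)
        assert np.allclose(M, R, atol=1e-8)
        assert np.allclose(t, shift, atol=1e-7)

    def test_noisy_fit_residual_matches_least_squares_theory(self, rng):
        pb = rng.uniform(0, 200, size=(200, 2))
        noise = rng.normal(0, 0.1, size=(200, 2))
        pa = pb + [1.0, 2.0] + noise
        M, t = estimate_affine(pb, pa)
        resid = pa - apply_affine(pb, (M, t))
        rms = np.sqrt((resid**2).sum(axis=1).mean())
        # per-pair residual RMS ≈ σ√2 for 2-d Gaussian noise
        assert rms == pytest.approx(0.1 * np.sqrt(2), rel=0.2)

    def test_too_few_or_collinear_pairs_rejected(self):
        with pytest.raises(AlignmentError):
            estimate_affine(np.array([[0.0, 0], [1, 1]]), np.array([[0.0, 0], [1, 1]]))
        line = np.array([[0.0, 0], [1, 1], [2, 2], [3, 3]])
        with pytest.raises(AlignmentError):
            estimate_affine(line, line)


class TestMatchPatterns:
    def test_identical_sets_fully_matched_at_zero_distance(self, rng):
        xy = rng.uniform(0, 100, size=(150, 2))
        A = make_set(xy, "A", id_prefix="a")
        B = make_set(xy, "B", id_prefix="b")
        m = match_patterns(A, B, MatchConfig(align_mode="none"))
        assert m.n_pairs == 150
        assert not m.unmatched_A and not m.unmatched_B
        assert not m.edged_out_A and not m.edged_out_B
        assert all(d == 0.0 for _, _, d in m.pairs)

    def test_conflict_resolved_by_smallest_distance(self):
        # both a0 and a1 want b0; a0 wins (distance 1 < 2), a1 finds no
        # second-round candidate and stays unmatched
        A = make_set([[0.0, 0.0], [0.0, 3.0]], "A", roi_bounds=(-10, -10, 10, 10), id_prefix="a")
        B = make_set([[0.0, 1.0]], "B", roi_bounds=(-10, -10, 10, 10), id_prefix="b")
        m = match_patterns(A, B, MatchConfig(align_mode="none"))
        assert m.pairs == [("a0", "b0", pytest.approx(1.0))]
        assert m.unmatched_A == {"a1"}
        assert not m.edged_out_A and not m.unmatched_B

    def test_conflict_loser_rematches_in_second_round(self):
        A = make_set([[0.0, 0.0], [0.0, 1.0]], "A", roi_bounds=(-10, -10, 10, 10), id_prefix="a")
        B = make_set([[0.0, 0.4], [0.0, 2.0]], "B", roi_bounds=(-10, -10, 10, 10), id_prefix="b")
        m = match_patterns(A, B, MatchConfig(align_mode="none"))
        got = {(a, b): (pytest.approx(d), r) for (a, b, d), r in zip(m.pairs, m.round_of_match)}
        # round 1: a0→b0 (0.4) beats a1→b0 (0.6); round 2: a1→b1 (1.0)
        assert set(got) == {("a0", "b0"), ("a1", "b1")}
        assert got[("a0", "b0")][1] == 1
        assert got[("a1", "b1")][1] == 2

    def test_matches_brute_force_on_random_instances(self, rng):
        cfg = MatchConfig(align_mode="none")
        for trial in range(250):
            na, nb = rng.integers(0, 30, size=2)
            xa = rng.uniform(0, 40, size=(na, 2))
            xb = rng.uniform(0, 40, size=(nb, 2))
            A = make_set(xa, "A", roi_bounds=(0, 0, 40, 40), id_prefix="a")
            B = make_set(xb, "B", roi_bounds=(0, 0, 40, 40), id_prefix="b")
            m = match_patterns(A, B, cfg)
            expected = brute_force_match(xa, A.ids, xb, B.ids)
            assert {(a, b) for a, b, _ in m.pairs} == expected
            # one-to-one + distance bound invariants
            ids_a = [a for a, _, _ in m.pairs]
            ids_b = [b for _, b, _ in m.pairs]
            assert len(set(ids_a)) == len(ids_a) and len(set(ids_b)) == len(ids_b)
            assert all(d <= 5 * np.sqrt(2) + 1e-12 for _, _, d in m.pairs)

    def test_window_is_chebyshev_square_not_euclidean_ball(self):
        # corner of the 10 μm window: offset (4.9, 4.9) is inside the square
        # though its Euclidean distance 6.93 exceeds the half-window 5
        A = make_set([[0.0, 0.0]], "A", roi_bounds=(-20, -20, 20, 20), id_prefix="a")
        B = make_set([[4.9, 4.9]], "B", roi_bounds=(-20, -20, 20, 20), id_prefix="b")
        m = match_patterns(A, B, MatchConfig(align_mode="none"))
        assert m.n_pairs == 1
        # offset (5.1, 0) is outside the square window
        B2 = make_set([[5.1, 0.0]], "B", roi_bounds=(-20, -20, 20, 20), id_prefix="b")
        m2 = match_patterns(A, B2, MatchConfig(align_mode="none"))
        assert m2.n_pairs == 0

    def test_symmetry_under_argument_swap(self, rng):
        xy = rng.uniform(0, 100, size=(120, 2))
        xb = xy[: 100] + rng.normal(0, 0.3, size=(100, 2))
        A = make_set(xy, "A", roi_bounds=(-5, -5, 105, 105), id_prefix="a")
        B = make_set(xb, "B", roi_bounds=(-5, -5, 105, 105), id_prefix="b")
        cfg = MatchConfig(align_mode="none")
        m_ab = match_patterns(A, B, cfg)
        m_ba = match_patterns(B, A, cfg)
        assert {(a, b) for a, b, _ in m_ab.pairs} == {(a, b) for b, a, _ in m_ba.pairs}

    def test_empty_inputs_yield_empty_result(self):
        A = make_set(np.empty((0, 2)), "A")
        B = make_set([[1.0, 1.0]], "B", roi_bounds=(0, 0, 2, 2), id_prefix="b")
        m = match_patterns(A, B, MatchConfig(align_mode="none"))
        assert m.n_pairs == 0 and m.unmatched_B == {"b0"}

    def test_shifted_replica_realigned_and_fully_matched(self, rng):
        xy = rng.uniform(5, 95, size=(300, 2))
        A = make_set(xy, "A", roi_bounds=(0, 0, 100, 100), id_prefix="a")
        B = make_set(xy + [2.0, -1.5], "B", roi_bounds=(2.0, -1.5, 102.0, 98.5), id_prefix="b")
        m = match_patterns(A, B, MatchConfig(align_mode="translation"))
        assert m.n_pairs == 300
        assert max(d for _, _, d in m.pairs) < 1e-6
        assert m.transform == pytest.approx((-2.0, 1.5), abs=1e-6)

    def test_edged_out_nuclei_outside_roi_overlap(self):
        # both ROIs cut at the same scanner coordinates, tissue shifted +4 μm
        # in B: after alignment B's window covers x ∈ [-4, 96] of A's frame,
        # so the A nucleus at x=98 had no chance of a partner → edged-out
        xa = np.array([[1.0, 50.0], [50.0, 50.0], [98.0, 50.0]])
        xb = np.array([[5.0, 50.0], [54.0, 50.0]])
        A = make_set(xa, "A", roi_bounds=(0, 0, 100, 100), id_prefix="a")
        B = make_set(xb, "B", roi_bounds=(0, 0, 100, 100), id_prefix="b")
        m = match_patterns(A, B, MatchConfig(align_mode="translation"))
        assert {(a, b) for a, b, _ in m.pairs} == {("a0", "b0"), ("a1", "b1")}
        assert m.transform == pytest.approx((-4.0, 0.0), abs=1e-9)
        assert m.edged_out_A == {"a2"} and not m.unmatched_A

    def test_planted_correspondence_recovered_exactly(self):
        # low jitter relative to the hard-core spacing: every reported pair
        # must coincide with the generator's correspondence map
        for seed in range(20):
            cfg = SyntheticScanConfig(
                n_nuclei=300, seed=seed, min_separation_um=4.0,
                jitter_sd_um=0.3, p_miss=0.0, fp_rate_per_um2=0.0,
                shift_um=(0.0, 0.0),
            )
            truth = generate_ground_truth(cfg)
            dsa, ca = simulate_scan(truth, cfg, replicate_seed=1000 + seed)
            dsb, cb = simulate_scan(truth, cfg, replicate_seed=2000 + seed)
            planted = {
                (ca[t], cb[t])
                for t in ca
                if ca[t] not in (None, "outside") and cb[t] not in (None, "outside")
            }
            m = match_patterns(dsa, dsb, MatchConfig())
            assert {(a, b) for a, b, _ in m.pairs} == planted


class TestMatchingPercentages:
    def test_perfect_match_is_100_0_0(self, rng):
        xy = rng.uniform(0, 50, size=(100, 2))
        A = make_set(xy, "A", id_prefix="a")
        B = make_set(xy, "B", id_prefix="b")
        m = match_patterns(A, B, MatchConfig(align_mode="none"))
        p = matching_percentages(m, 100, 100)
        assert p.as_tuple() == (100.0, 0.0, 0.0)

    def test_pooled_arithmetic(self):
        # 90 pairs, 5+9 unmatched → 180/194 = 92.78...
        from replicascan.register import MatchResult

        m = MatchResult(
            pairs=[(f"a{i}", f"b{i}", 0.1) for i in range(90)],
            unmatched_A={f"a{i}" for i in range(90, 95)},
            unmatched_B={f"b{i}" for i in range(90, 99)},
            edged_out_A=set(), edged_out_B=set(),
            transform=None, round_of_match=[1] * 90,
        )
        p = matching_percentages(m, 95, 99)
        assert p.matched_pct == pytest.approx(100 * 180 / 194)
        assert p.unmatched_pct == pytest.approx(100 * 14 / 194)
        assert p.edged_out_pct == 0.0
        assert sum(p.as_tuple()) == pytest.approx(100.0, abs=1e-9)

    def test_empty_comparison_rejected(self):
        from replicascan.register import MatchResult

        m = MatchResult([], set(), set(), set(), set(), None, [])
        with pytest.raises(ZeroDivisionError):
            matching_percentages(m, 0, 0)

    def test_simulated_dropout_matches_correspondence_expectation(self):
        # with drop-out on both sides and tiny jitter, matched_pct should sit
        # near the value implied by the generator's own correspondence maps
        got, expected = [], []
        for seed in range(5):
            cfg = SyntheticScanConfig(
                n_nuclei=500, seed=seed, min_separation_um=3.0,
                jitter_sd_um=0.2, p_miss=0.05, fp_rate_per_um2=0.0,
                shift_um=(0.0, 0.0),
            )
            truth = generate_ground_truth(cfg)
            dsa, ca = simulate_scan(truth, cfg, replicate_seed=31 + seed)
            dsb, cb = simulate_scan(truth, cfg, replicate_seed=77 + seed)
            m = match_patterns(dsa, dsb, MatchConfig())
            p = matching_percentages(m, len(dsa), len(dsb))
            both = sum(
                1 for t in ca
                if ca[t] not in (None, "outside") and cb[t] not in (None, "outside")
            )
            got.append(p.matched_pct)
            expected.append(100 * 2 * both / (len(dsa) + len(dsb)))
        assert np.mean(got) == pytest.approx(np.mean(expected), abs=2.0)

    @given(st.integers(0, 200), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 20), st.integers(0, 20))
    @settings(max_examples=100, deadline=None)
    def test_percentages_always_sum_to_100(self, k, ua, ub, ea, eb):
        from replicascan.register import MatchResult

        m = MatchResult(
            pairs=[(f"a{i}", f"b{i}", 0.0) for i in range(k)],
            unmatched_A={f"ua{i}" for i in range(ua)},
            unmatched_B={f"ub{i}" for i in range(ub)},
            edged_out_A={f"ea{i}" for i in range(ea)},
            edged_out_B={f"eb{i}" for i in range(eb)},
            transform=None, round_of_match=[1] * k,
        )
        n_a, n_b = k + ua + ea, k + ub + eb
        if n_a + n_b == 0:
            return
        p = matching_percentages(m, n_a, n_b)
        assert sum(p.as_tuple()) == pytest.approx(100.0, abs=1e-9)

    def test_degradation_monotone_in_p_miss_and_fp_rate(self):
        def mean_matched(p_miss, fp_rate):
            vals = []
            for seed in range(10):
                cfg = SyntheticScanConfig(
                    n_nuclei=300, seed=seed, min_separation_um=3.0,
                    jitter_sd_um=0.2, p_miss=p_miss, fp_rate_per_um2=fp_rate,
                    shift_um=(0.0, 0.0),
                )
                truth = generate_ground_truth(cfg)
                dsa, _ = simulate_scan(truth, cfg, replicate_seed=500 + seed)
                dsb, _ = simulate_scan(truth, cfg, replicate_seed=900 + seed)
                m = match_patterns(dsa, dsb, MatchConfig())
                vals.append(matching_percentages(m, len(dsa), len(dsb)).matched_pct)
            return np.mean(vals)

        by_miss = [mean_matched(p, 0.0) for p in (0.0, 0.05, 0.1)]
        assert by_miss[0] >= by_miss[1] >= by_miss[2]
        by_fp = [mean_matched(0.0, r) for r in (0.0, 0.002, 0.004)]
        assert by_fp[0] >= by_fp[1] >= by_fp[2]
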