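"""Contact-map statistics vs brute-force enumeration on hand instances."""

import numpy as np
import pytest

from chromoswitch import (ContactMap, SegmentSpec, call_compartments,
                          cluster_stages, contact_prob_curve, delta_p_frames,
                          delta_p_reference, fit_pl_slope, insulation_score,
                          make_gene_density, make_target_map, obs_over_exp,
                          tad_boundary_overlap, DegenerateCompartmentError)
from chromoswitch.maps import GeneDensityTrack


def map_of(matrix, res=100_000):
    m = np.asarray(matrix, dtype=float)
    return ContactMap(m, SegmentSpec.desk_scale(m.shape[0], res))


def symmetric_random_map(n, rng, res=100_000):
    p = rng.uniform(0.01, 0.9, (n, n))
    p = 0.5 * (p + p.T)
    np.fill_diagonal(p, 1.0)
    return map_of(p, res)


class TestContactProbCurve:
    def test_power_law_construction_is_recovered_exactly(self):
        cmap = make_target_map(30, decay_exponent=1.0, amplitude=1.0)
        l_bp, p = contact_prob_curve(cmap)
        assert p == pytest.approx((l_bp / 100_000.0) ** -1)

    def test_flat_map_gives_flat_curve(self):
        c = 0.37
        p = np.full((8, 8), c)
        cmap = map_of(p)
        _, curve = contact_prob_curve(cmap)
        assert curve == pytest.approx(np.full(7, c))

    def test_matches_per_diagonal_brute_force(self, rng):
        cmap = symmetric_random_map(5, rng)
        _, curve = contact_prob_curve(cmap)
        for k in range(1, 5):
            vals = [cmap.probs[i, i + k] for i in range(5 - k)]
            assert curve[k - 1] == pytest.approx(np.mean(vals))


class TestPlSlope:
    @pytest.mark.parametrize("gamma", [1.0, 1.5])
    def test_planted_exponent_recovered(self, gamma):
        cmap = make_target_map(100, decay_exponent=gamma, amplitude=1.0)
        l_bp, p = contact_prob_curve(cmap)
        slope = fit_pl_slope(l_bp, p, (500_000, 7_000_000))
        assert slope == pytest.approx(-gamma, abs=1e-9)

    def test_flat_curve_gives_zero_slope(self):
        l = np.geomspace(1e5, 1e7, 30)
        assert fit_pl_slope(l, np.full(30, 0.2), (2e5, 8e6)) == pytest.approx(0.0)

    def test_nonpositive_values_rejected(self):
        l = np.geomspace(1e5, 1e7, 30)
        p = np.full(30, 0.2)
        p[10] = 0.0
        with pytest.raises(ValueError):
            fit_pl_slope(l, p, (1e5, 1e7))


class TestDeltaPFrames:
    def test_identical_frames_give_zero(self, rng):
        m = symmetric_random_map(6, rng)
        d = delta_p_frames([m, m, m], "total", normalize=False)
        assert np.all(d == 0.0)

    def test_near_zero_frame_gives_raw_value_one(self):
        p = np.full((4, 4), 0.5)
        tiny = np.zeros((4, 4))
        d = delta_p_frames([map_of(p), map_of(tiny)], "total", normalize=False)
        # sum |P - 0| / sum P = 1 from the nonzero frame's side
        # (diagonals are pinned to 1 and excluded by the range mask)
        assert d[0, 1] == pytest.approx(1.0)

    def test_matches_direct_formula_on_hand_frames(self, rng):
        frames = [symmetric_random_map(4, rng) for _ in range(3)]
        raw = delta_p_frames(frames, "total", normalize=False)
        for I in range(3):
            for J in range(3):
                num = den = 0.0
                for i in range(4):
                    for j in range(4):
                        if i == j:
                            continue
                        num += abs(frames[I].probs[i, j] - frames[J].probs[i, j])
                        den += frames[I].probs[i, j]
                assert raw[I, J] == pytest.approx(num / den)

    def test_normalized_output_spans_unit_interval(self, rng):
        frames = [symmetric_random_map(6, rng) for _ in range(4)]
        d = delta_p_frames(frames, "total")
        assert d.min() == 0.0 and d.max() == 1.0

    def test_range_filters_partition_the_pairs(self, rng):
        # local: |i-j| < 20 bins at 100 kb (2 Mb); nonlocal: the rest
        frames = [symmetric_random_map(30, rng) for _ in range(2)]
        d_tot = delta_p_frames(frames, "total", normalize=False)
        d_loc = delta_p_frames(frames, "local", normalize=False)
        d_non = delta_p_frames(frames, "nonlocal", normalize=False)
        assert not np.allclose(d_loc, d_non)
        assert d_tot[0, 1] == pytest.approx(
            (d_loc[0, 1] * sum_local(frames[0]) + d_non[0, 1] * sum_nonlocal(frames[0]))
            / (sum_local(frames[0]) + sum_nonlocal(frames[0])))


def sum_local(cmap, thresh=20):
    n = cmap.n_bins
    tot = 0.0
    for i in range(n):
        for j in range(n):
            if 0 < abs(i - j) < thresh:
                tot += cmap.probs[i, j]
    return tot


def sum_nonlocal(cmap, thresh=20):
    n = cmap.n_bins
    tot = 0.0
    for i in range(n):
        for j in range(n):
            if abs(i - j) >= thresh:
                tot += cmap.probs[i, j]
    return tot


class TestDeltaPReference:
    def test_reference_equal_to_frame_gives_zero(self, rng):
        m = symmetric_random_map(6, rng)
        assert delta_p_reference([m], m)[0] == 0.0

    def test_doubled_flat_reference_gives_one(self):
        c = 0.3
        frame = map_of(np.full((5, 5), c))
        ref = map_of(np.full((5, 5), 2 * c))
        assert delta_p_reference([frame], ref)[0] == pytest.approx(1.0)


class TestClusterStages:
    def _block_series(self, boundaries, n_frames, rng, spread=0.02):
        """Piecewise-constant frame dissimilarity with planted change points."""
        levels = np.zeros(n_frames)
        for b in boundaries:
            levels[b:] += 1.0
        d = np.abs(levels[:, None] - levels[None, :])
        d = d / d.max() + rng.normal(0, spread, (n_frames, n_frames))
        d = np.clip(0.5 * (d + d.T), 0, None)
        np.fill_diagonal(d, 0.0)
        return d

    def test_two_well_separated_blocks_split_at_truth(self, rng):
        d = self._block_series([10], 20, rng, spread=0.0)
        stages = cluster_stages(d, d, n_stages=2)
        assert stages.n_stages == 2
        assert list(stages.boundaries) == [10]

    def test_planted_change_points_recovered(self, rng):
        bounds = [5, 11, 18, 26, 33, 41, 50]
        d = self._block_series(bounds, 60, rng, spread=0.01)
        stages = cluster_stages(d, d, n_stages=8)
        assert stages.n_stages == 8
        found = stages.boundaries
        for b in bounds:
            assert np.min(np.abs(found - b)) <= 1

    def test_stages_are_contiguous_blocks(self, rng):
        d = self._block_series([7, 14], 30, rng)
        stages = cluster_stages(d, d, n_stages=5)
        labels = stages.frame_to_stage
        # label sequence must be non-decreasing block ids after remapping
        change_points = np.flatnonzero(np.diff(labels)) + 1
        assert len(change_points) == 4
        assert stages.stage_midframes().size == 5

    def test_more_stages_than_frames_rejected(self, rng):
        d = self._block_series([2], 5, rng)
        with pytest.raises(ValueError):
            cluster_stages(d, d, n_stages=9)


class TestObsOverExp:
    def test_distance_only_map_gives_ones(self):
        cmap = make_target_map(20, decay_exponent=1.0, amplitude=0.9)
        oe = obs_over_exp(cmap)
        assert np.nanmax(np.abs(oe - 1.0)) < 1e-12

    def test_symmetry_preserved(self, rng):
        oe = obs_over_exp(symmetric_random_map(7, rng))
        assert np.allclose(oe, oe.T, equal_nan=True)

    def test_matches_per_diagonal_brute_force(self, rng):
        cmap = symmetric_random_map(5, rng)
        oe = obs_over_exp(cmap)
        for i in range(5):
            for j in range(5):
                k = abs(i - j)
                vals = [cmap.probs[a, a + k] for a in range(5 - k)]
                assert oe[i, j] == pytest.approx(cmap.probs[i, j] / np.mean(vals))


class TestCompartments:
    def test_orientation_flips_with_inverted_gene_track(self):
        from chromoswitch.maps import CompartmentProfile
        labels = np.where((np.arange(80) // 10) % 2 == 0, 1.0, -1.0)
        profile = CompartmentProfile(labels)
        cmap = make_target_map(80, compartment=profile, plaid_strength=0.3,
                               noise_level=0.02, seed=1)
        genes_a = GeneDensityTrack(np.where(labels > 0, 10.0, 1.0))
        genes_b = GeneDensityTrack(np.where(labels > 0, 1.0, 10.0))
        called_a = call_compartments(cmap, genes_a)
        called_b = call_compartments(cmap, genes_b)
        assert np.all(called_a.labels == -called_b.labels)

    def test_distance_only_map_is_degenerate(self):
        cmap = make_target_map(30, decay_exponent=1.0, amplitude=0.9)
        with pytest.raises(DegenerateCompartmentError):
            call_compartments(cmap)

    def test_small_maps_rejected(self, rng):
        with pytest.raises(ValueError):
            call_compartments(symmetric_random_map(5, rng))


class TestInsulation:
    def test_uniform_map_has_flat_track_and_no_boundaries(self):
        cmap = map_of(np.full((30, 30), 0.4))
        track = insulation_score(cmap, window_bins=3)
        interior = track.scores[3:-3]
        assert np.nanmax(np.abs(interior)) < 1e-12
        assert track.boundaries.size == 0

    def test_two_block_map_has_single_boundary_at_junction(self):
        n = 30
        p = np.full((n, n), 0.05)
        p[:15, :15] = 0.8
        p[15:, 15:] = 0.8
        np.fill_diagonal(p, 1.0)
        track = insulation_score(map_of(p), window_bins=4)
        assert track.boundaries.size >= 1
        # the strongest minimum sits where the two blocks meet
        best = track.boundaries[np.argmin(track.scores[track.boundaries])]
        assert abs(best - 15) <= 1

    def test_track_length_and_edge_masking(self, rng):
        cmap = symmetric_random_map(25, rng)
        track = insulation_score(cmap, window_bins=5)
        assert track.scores.size == 25
        assert np.isnan(track.scores[:5]).all()
        assert np.isnan(track.scores[-5:]).all()

    def test_oversized_window_rejected(self, rng):
        with pytest.raises(ValueError):
            insulation_score(symmetric_random_map(10, rng), window_bins=5)


class TestTadBoundaryOverlap:
    def test_identical_lists_overlap_fully(self):
        res = tad_boundary_overlap([3, 9, 17], [3, 9, 17], tol_bins=1)
        assert res["n_overlap"] == 3
        assert res["frac_a"] == 1.0 and res["frac_b"] == 1.0

    def test_disjoint_lists_do_not_overlap(self):
        res = tad_boundary_overlap([0, 10], [50, 60], tol_bins=2)
        assert res["n_overlap"] == 0

    def test_hand_matched_case(self):
        res = tad_boundary_overlap([10, 20, 30], [11, 29, 50], tol_bins=1)
        assert res["n_overlap"] == 2
        assert res["frac_a"] == pytest.approx(2 / 3)
        assert res["frac_b"] == pytest.approx(2 / 3)

    def test_each_boundary_used_once(self):
        # both entries of `a` are within tol of the single entry of `b`
        res = tad_boundary_overlap([10, 11], [10], tol_bins=1)
        assert res["n_overlap"] == 1
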