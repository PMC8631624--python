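"""d_rms metric, structure clustering, and the switching protocol."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from chromoswitch import (Conformation, DynamicsParams, PolymerParams,
                          cluster_ensemble, pairwise_drms, run_switch,
                          zero_alpha)
from chromoswitch.maxent import Landscape
from chromoswitch.switching import drms_matrix

from conftest import random_chain


class TestPairwiseDrms:
    def test_identical_structures_have_zero_distance(self, rng):
        a = Conformation(random_chain(10, rng))
        assert pairwise_drms(a, a) == 0.0

    def test_rigid_motion_and_reflection_invariance(self, rng):
        x = random_chain(10, rng)
        rot = Rotation.from_rotvec([0.5, 1.0, -0.2]).as_matrix()
        y = (-x) @ rot.T + np.array([3.0, 4.0, 5.0])
        assert pairwise_drms(Conformation(x), Conformation(y)) < 1e-12

    def test_matches_bruteforce_on_four_bead_toys(self):
        xa = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        xb = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        total = 0.0
        count = 0
        for i in range(4):
            for j in range(i + 1, 4):
                da = np.linalg.norm(xa[j] - xa[i])
                db = np.linalg.norm(xb[j] - xb[i])
                total += (da - db) ** 2
                count += 1
        expected = np.sqrt(total / count)
        got = pairwise_drms(Conformation(xa), Conformation(xb))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_size_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            pairwise_drms(Conformation(random_chain(5, rng)),
                          Conformation(random_chain(6, rng)))

    def test_condensed_matrix_agrees_with_pairwise_calls(self, rng):
        ens = [Conformation(random_chain(6, rng)) for _ in range(4)]
        cond = drms_matrix(ens)
        k = 0
        for i in range(4):
            for j in range(i + 1, 4):
                assert cond[k] == pytest.approx(pairwise_drms(ens[i], ens[j]))
                k += 1


class TestClusterEnsemble:
    def test_identical_copies_form_one_full_cluster(self, rng):
        x = random_chain(8, rng)
        ens = [Conformation(x.copy()) for _ in range(50)]
        cs = cluster_ensemble(ens, cutoff=3.0)
        assert cs.n_clusters == 1
        assert cs.populations[0] == pytest.approx(1.0)

    def test_two_separated_groups_are_split(self, rng):
        compact = random_chain(10, rng) * 0.3
        rod = np.zeros((10, 3))
        rod[:, 0] = np.arange(10)
        ens = ([Conformation(compact + rng.normal(0, 0.01, compact.shape))
                for _ in range(10)] +
               [Conformation(rod + rng.normal(0, 0.01, rod.shape))
                for _ in range(10)])
        cs = cluster_ensemble(ens, cutoff=1.0)
        assert cs.n_clusters == 2
        assert sorted(np.bincount(cs.labels)[1:]) == [10, 10]

    def test_representative_count_follows_population_rule(self, rng):
        # 3 groups of sizes 12, 6 and 2 with a 25% population threshold:
        # only the first two qualify, two picks each
        bases = [random_chain(8, rng) * s for s in (0.3, 1.0, 2.5)]
        ens = []
        for base, size in zip(bases, (12, 6, 2)):
            for _ in range(size):
                ens.append(Conformation(base + rng.normal(0, 0.01, base.shape)))
        cs = cluster_ensemble(ens, cutoff=1.0, pop_threshold=0.25,
                              picks_per_cluster=2)
        assert len(cs.representatives) == 4

    def test_unreachable_threshold_raises(self, rng):
        ens = [Conformation(random_chain(6, rng)) for _ in range(5)]
        with pytest.raises(ValueError):
            cluster_ensemble(ens, cutoff=3.0, pop_threshold=1.5)


def _toy_landscapes(rng, n=16):
    params = PolymerParams().with_rc_for(n)
    attract = zero_alpha(n)
    iu = np.triu_indices(n, k=2)
    attract[iu] = -1.0
    attract += attract.T
    pre = Landscape(zero_alpha(n), params, "open")
    post = Landscape(attract, params, "compact")
    return pre, post


class TestRunSwitch:
    def test_coordinates_unchanged_across_the_switch(self, rng):
        pre, post = _toy_landscapes(rng)
        start = Conformation(random_chain(16, rng))
        runs = run_switch([start], pre, post, t_pre=1.0, t_post=2.0,
                          master_seed=3, n_snapshots=10)
        run = runs[0]
        # the last pre-phase frame IS the first post-phase frame, bitwise
        assert np.array_equal(run.pre_trajectory.frames[-1],
                              run.post_trajectory.frames[0])
        assert run.post_trajectory.times[0] == 0.0

    def test_seed_splitting_gives_distinct_but_reproducible_runs(self, rng):
        pre, post = _toy_landscapes(rng)
        start = Conformation(random_chain(16, rng))
        runs_a = run_switch([start], pre, post, 0.5, 0.5, master_seed=3,
                            n_runs=2, n_snapshots=5)
        runs_b = run_switch([start], pre, post, 0.5, 0.5, master_seed=3,
                            n_runs=2, n_snapshots=5)
        assert np.array_equal(runs_a[0].post_trajectory.frames,
                              runs_b[0].post_trajectory.frames)
        assert not np.array_equal(runs_a[0].post_trajectory.frames,
                                  runs_a[1].post_trajectory.frames)

    def test_attractive_switch_compacts_the_chain(self, rng):
        from chromoswitch import shape_descriptors
        pre, post = _toy_landscapes(rng)
        start = Conformation(random_chain(16, rng))
        runs = run_switch([start], pre, post, t_pre=5.0, t_post=25.0,
                          master_seed=1, n_snapshots=20)
        post_traj = runs[0].post_trajectory
        rg_start = shape_descriptors(Conformation(post_traj.frames[0])).Rg
        rg_end = shape_descriptors(Conformation(post_traj.frames[-1])).Rg
        assert rg_end < rg_start

    def test_null_switch_changes_nothing_statistically(self, rng):
        # identical pre and post landscapes: the "transition" is a plain
        # continuation, so post-phase mean Rg stays within 2 SE of pre-phase
        from chromoswitch import shape_descriptors
        n = 16
        params = PolymerParams().with_rc_for(n)
        land = Landscape(zero_alpha(n), params, "same")
        starts = [Conformation(random_chain(n, rng)) for _ in range(4)]
        runs = run_switch(starts, land, land, t_pre=15.0, t_post=15.0,
                          master_seed=11, n_snapshots=20)
        pre_rg, post_rg = [], []
        for r in runs:
            # skip early pre frames (equilibration from the random start)
            pre_rg += [shape_descriptors(Conformation(f)).Rg
                       for f in r.pre_trajectory.frames[10:]]
            post_rg += [shape_descriptors(Conformation(f)).Rg
                        for f in r.post_trajectory.frames[1:]]
        pre_rg, post_rg = np.array(pre_rg), np.array(post_rg)
        se = np.sqrt(pre_rg.var() / 8 + post_rg.var() / 8)  # ~2 indep/run
        assert abs(post_rg.mean() - pre_rg.mean()) < 2 * se

    def test_size_mismatch_rejected(self, rng):
        pre, _ = _toy_landscapes(rng, 16)
        _, post = _toy_landscapes(rng, 12)
        with pytest.raises(ValueError):
            run_switch([Conformation(random_chain(16, rng))], pre, post,
                       1.0, 1.0)
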