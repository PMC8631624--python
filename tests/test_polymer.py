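"""Energy-model tests: printed values, continuity, and the force oracle."""

import math

import numpy as np
import pytest

from chromoswitch import (Conformation, PolymerParams, OverstretchedBondError,
                          confinement_radius, eval_angle, eval_confinement,
                          eval_contact_prob, eval_fene, eval_hardcore,
                          eval_restraint, eval_softcore, eval_vlj,
                          total_energy_forces, zero_alpha)
from chromoswitch import _kernels
from chromoswitch.polymer import validate_alpha

from conftest import random_alpha, random_chain

P = PolymerParams()
R0_SOFT = P.softcore_r0
LJ_CUT = 2.0 ** (1.0 / 6.0)


class TestPotentialValues:
    def test_lj_at_sigma_and_minimum(self):
        assert eval_vlj(1.0) == pytest.approx(1.0)
        assert eval_vlj(LJ_CUT) == pytest.approx(0.0, abs=1e-14)

    def test_lj_at_softcore_crossover_is_two(self):
        # r0 = sigma / ((1 + sqrt 2)/2)^(1/6) is chosen so V_LJ(r0) = 2 eps
        assert eval_vlj(R0_SOFT) == pytest.approx(2.0, abs=1e-12)

    def test_fene_zero_divergence_and_reference_value(self):
        assert eval_fene(0.0, P) == 0.0
        assert eval_fene(1.499999, P) > 1e2
        # -0.5 * 30 * 1.5^2 * ln(1 - (1/1.5)^2) evaluated independently
        assert eval_fene(1.0, P) == pytest.approx(-33.75 * math.log(1 - 1 / 2.25),
                                                  rel=1e-12)
        assert eval_fene(1.0, P) == pytest.approx(19.8378, abs=1e-4)
        with pytest.raises(OverstretchedBondError):
            eval_fene(1.5, P)

    def test_hardcore_matches_lj_inside_cutoff_and_vanishes_beyond(self):
        assert eval_hardcore(1.0, P) == pytest.approx(eval_vlj(1.0))
        assert eval_hardcore(LJ_CUT, P) == pytest.approx(0.0, abs=1e-14)
        assert eval_hardcore(2.0, P) == 0.0

    def test_angle_limits(self):
        assert eval_angle(math.pi, P) == pytest.approx(0.0, abs=1e-14)
        assert eval_angle(0.0, P) == pytest.approx(2 * P.Ka)   # 4.0 at defaults
        assert eval_angle(math.pi / 2, P) == pytest.approx(P.Ka)
        with pytest.raises(ValueError):
            eval_angle(-0.1, P)

    def test_softcore_plateau_maximum_is_four(self):
        # full overlap: 2 eps (1 + tanh(inf)) -> 4 eps, finite so chains cross
        assert eval_softcore(1e-3, P) == pytest.approx(4.0, abs=1e-12)
        assert eval_softcore(1e-6, P) == pytest.approx(4.0, abs=1e-12)

    def test_softcore_beyond_cutoff_is_zero(self):
        assert eval_softcore(1.5, P) == 0.0

    def test_contact_indicator_midpoint_and_decay(self):
        assert eval_contact_prob(P.r_contact, P) == pytest.approx(0.5)
        assert eval_contact_prob(50.0, P) == pytest.approx(0.0, abs=1e-12)
        # 1/mu inside the midpoint: (1 + tanh 1)/2
        expected = 0.5 * (1 + math.tanh(1.0))
        assert eval_contact_prob(P.r_contact - 1 / P.mu, P) == pytest.approx(expected)
        r = np.linspace(0.1, 5.0, 50)
        assert (np.diff(eval_contact_prob(r, P)) < 0).all()


class TestPiecewiseContinuity:
    @pytest.mark.parametrize("breakpoint", [R0_SOFT, LJ_CUT])
    def test_softcore_continuous_at_breakpoints(self, breakpoint):
        eps = 1e-9
        left = eval_softcore(breakpoint - eps, P)
        right = eval_softcore(breakpoint + eps, P)
        assert abs(left - right) < 1e-6
        # exact values at the joins
        if breakpoint == R0_SOFT:
            assert eval_softcore(breakpoint, P) == pytest.approx(2.0, abs=1e-12)

    def test_hardcore_continuous_at_cutoff(self):
        assert abs(eval_hardcore(LJ_CUT - 1e-9, P) - eval_hardcore(LJ_CUT + 1e-9, P)) < 1e-6


class TestRestraintAndConfinement:
    def test_zero_alpha_gives_zero_energy(self, rng):
        conf = Conformation(random_chain(8, rng))
        assert eval_restraint(conf, zero_alpha(8), P) == 0.0

    def test_single_pair_at_midpoint(self):
        x = np.zeros((4, 3))
        x[:, 0] = [0.0, 1.0, 2.0, 2.0 + P.r_contact]
        x[3] = [2.0, P.r_contact, 0.0]
        a = np.zeros((4, 4))
        a[1, 3] = a[3, 1] = 1.0
        conf = Conformation(x)
        r13 = np.linalg.norm(x[3] - x[1])
        expected = eval_contact_prob(r13, P)
        assert eval_restraint(conf, a, P) == pytest.approx(expected)

    def test_restraint_linear_in_alpha(self, rng):
        conf = Conformation(random_chain(10, rng))
        a = random_alpha(10, rng)
        e1 = eval_restraint(conf, a, P)
        assert eval_restraint(conf, 2 * a, P) == pytest.approx(2 * e1)

    def test_restraint_matches_bruteforce_sum(self, rng):
        n = 12
        conf = Conformation(random_chain(n, rng))
        a = random_alpha(n, rng)
        brute = 0.0
        for i in range(n):
            for j in range(i + 2, n):
                r = np.linalg.norm(conf.positions[j] - conf.positions[i])
                brute += a[i, j] * eval_contact_prob(r, P)
        assert eval_restraint(conf, a, P) == pytest.approx(brute, rel=1e-12)

    def test_alpha_validation_rejects_bonded_entries(self):
        a = np.zeros((5, 5))
        a[0, 1] = a[1, 0] = 1.0
        with pytest.raises(ValueError):
            validate_alpha(a)

    def test_confinement_zero_inside_and_harmonic_outside(self):
        x = np.zeros((3, 3))
        x[1, 0] = P.Rc            # exactly on the wall
        conf = Conformation(x)
        assert eval_confinement(conf, P) == 0.0
        x[2, 0] = P.Rc + 1.0      # one sigma outside: k_wall * 1^2
        assert eval_confinement(Conformation(x), P) == pytest.approx(P.k_wall)

    def test_confinement_radius_preserves_density(self):
        assert confinement_radius(857) == pytest.approx(9.7)
        ratio = confinement_radius(120) / 9.7
        assert ratio == pytest.approx((120 / 857) ** (1 / 3))


class TestForces:
    def test_straight_trimer_has_no_angle_force(self):
        x = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        _, f = total_energy_forces(Conformation(x), None, P)
        # bond forces along x cancel symmetrically; no transverse force
        assert np.abs(f[:, 1:]).max() < 1e-12

    def test_newtons_third_law(self, rng):
        x = random_chain(15, rng)
        a = random_alpha(15, rng)
        _, f = total_energy_forces(Conformation(x), a, P)
        scale = np.abs(f).max()
        assert np.abs(f.sum(axis=0)).max() < 1e-10 * max(scale, 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_forces_match_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        x = random_chain(n, rng)
        a = random_alpha(n, rng)
        params = PolymerParams().with_rc_for(n)
        _, f = total_energy_forces(Conformation(x), a, params)
        h = 1e-6
        scale = max(1.0, np.abs(f).max())
        for i in range(n):
            for d in range(3):
                xp = x.copy(); xp[i, d] += h
                xm = x.copy(); xm[i, d] -= h
                ep = total_energy_forces(Conformation(xp), a, params)[0]["total"]
                em = total_energy_forces(Conformation(xm), a, params)[0]["total"]
                fd = -(ep - em) / (2 * h)
                assert abs(fd - f[i, d]) / scale < 1e-5

    def test_compiled_kernel_matches_reference(self, rng):
        n = 25
        x = random_chain(n, rng)
        a = random_alpha(n, rng, scale=5.0)
        params = PolymerParams().with_rc_for(n)
        f = np.empty_like(x)
        g_table, g_inv_h, _ = _kernels.restraint_force_table(
            params.mu, params.r_contact)
        status = _kernels.pair_forces(
            x, a, params.eps, params.sigma, params.Kb, params.R0_fene,
            params.Ka, params.Rc, params.mu, params.r_contact,
            params.softcore_r0, params.k_wall, g_table, g_inv_h, f)
        assert status == _kernels.OK
        _, fref = total_energy_forces(Conformation(x), a, params)
        # kernel truncates the restraint force at r_contact + 8/mu
        assert np.abs(f - fref).max() < 1e-4

    def test_overstretched_bond_reports_index(self):
        x = np.zeros((4, 3))
        x[:, 0] = [0.0, 1.0, 2.6, 3.6]   # bond 1 has length 1.6 > R0
        with pytest.raises(OverstretchedBondError) as exc:
            total_energy_forces(Conformation(x), None, P)
        assert exc.value.bond_index == 1
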