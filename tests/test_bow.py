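"""Bow tension calibration: entropic route and rigid base-pair route."""

import numpy as np
import pytest

from dnabow.constants import DS_RISE, KBT
from dnabow.bow import (
    DEFAULT_ARC_LENGTHS_BP,
    ExtensionStats,
    RigidBasePairChain,
    bow_force_estimate,
    bow_self_consistent,
    rbp_ground_state,
    rbp_path,
    rbp_restrained_minimize,
    register_scan,
)
from dnabow.polymer import LinearFER, RadialDistribution, WLCModel, wlc_radial_pdf


def gaussian_dist(mu=10.0, sd=1.0):
    x = np.linspace(mu - 7 * sd, mu + 7 * sd, 4001)
    return RadialDistribution(x=x, p=np.exp(-((x - mu) ** 2) / (2 * sd**2)))


class TestBowForceEstimate:
    def test_gaussian_closed_form(self):
        # f = kBT (mu - xbar)/sd^2 as a pushing tension; sigma_f = kBT sd(x)/sd^2
        f, sigma = bow_force_estimate(gaussian_dist(), ExtensionStats(9.0, 0.5, 100))
        assert f == pytest.approx(KBT, rel=1e-6)
        assert sigma == pytest.approx(KBT * 0.5, rel=1e-6)

    def test_zero_spread_zero_uncertainty(self):
        f, sigma = bow_force_estimate(gaussian_dist(), ExtensionStats(9.0, 0.0, 100))
        assert sigma == 0.0

    def test_support_guard(self):
        with pytest.raises(ValueError):
            bow_force_estimate(gaussian_dist(), ExtensionStats(3.5, 1.0, 10))

    def test_error_propagation_matches_two_point_difference(self, arc_74):
        dist = wlc_radial_pdf(arc_74, np.linspace(0, arc_74.contour_length, 8001))
        stats = ExtensionStats(10.0, 0.4, 1000)
        f, sigma = bow_force_estimate(dist, stats)
        spline = dist.log_spline()
        two_point = abs(
            KBT * spline.derivative()(stats.mean + stats.sd)
            - KBT * spline.derivative()(stats.mean - stats.sd)
        ) / 2
        assert sigma == pytest.approx(two_point, rel=0.05)


class TestSelfConsistent:
    def test_inextensible_string_limit(self, arc_74):
        dist = wlc_radial_pdf(arc_74, np.linspace(0, arc_74.contour_length, 8001))
        rest = 6.5
        x_star, f_star = bow_self_consistent(dist, LinearFER(a=1e9, b=rest))
        assert x_star == pytest.approx(rest, abs=1e-4)
        spline = dist.log_spline()
        assert f_star == pytest.approx(float(KBT * spline.derivative()(rest)), rel=1e-3)

    def test_matches_free_energy_minimization(self, arc_74):
        # total free energy -kBT log p_arc(x) + a (x-b)^2 / 2, dense grid argmin
        string = LinearFER.from_per_nt(kappa=30.7, x0=0.21, n=15)
        dist = wlc_radial_pdf(arc_74, np.linspace(0, arc_74.contour_length, 8001))
        x_star, _ = bow_self_consistent(dist, string)
        grid = np.linspace(string.b + 1e-3, dist.mode, 20001)
        spline = dist.log_spline()
        total = -KBT * spline(grid) + 0.5 * string.a * (grid - string.b) ** 2
        assert grid[np.argmin(total)] == pytest.approx(x_star, abs=2e-3)

    def test_force_decreases_with_arc_length(self):
        string = LinearFER.from_per_nt(kappa=30.7, x0=0.21, n=15)
        forces = []
        for bp in DEFAULT_ARC_LENGTHS_BP:
            arc = WLCModel(bp * DS_RISE, 50.0)
            forces.append(bow_self_consistent(arc, string)[1])
        assert np.all(np.diff(forces) < 0)
        # qualitative gate: the seven bows span roughly 2-6 pN
        assert 1.5 < forces[-1] < 3.0
        assert 4.5 < forces[0] < 7.0

    def test_no_equilibrium_raises(self, arc_74):
        dist = wlc_radial_pdf(arc_74, np.linspace(0, arc_74.contour_length, 4001))
        with pytest.raises(ValueError):
            bow_self_consistent(dist, LinearFER(a=1e9, b=dist.mode + 1.0))


class TestRigidBasePair:
    def test_straight_twist_only_chain(self):
        chain = RigidBasePairChain.straight(30)
        path = rbp_ground_state(chain)
        assert np.linalg.norm(path[-1] - path[0]) == pytest.approx(30 * chain.rise, abs=1e-12)

    def test_constant_roll_forms_circular_arc(self):
        gamma = 4.0  # deg per step
        n = 40
        chain = RigidBasePairChain(
            roll0=np.full(n, gamma), tilt0=np.zeros(n), twist0=np.zeros(n),
            beta_roll=np.full(n, 0.02), beta_tilt=np.full(n, 0.02),
            beta_twist=np.full(n, 0.02),
        )
        path = rbp_ground_state(chain)
        g = np.deg2rad(gamma)
        R = chain.rise / (2 * np.sin(g / 2))  # circumradius of the polygon arc
        expected = 2 * R * np.sin(n * g / 2)
        assert np.linalg.norm(path[-1] - path[0]) == pytest.approx(expected, rel=1e-6)

    def test_matches_explicit_transform_product(self, rng):
        n = 12
        chain = RigidBasePairChain(
            roll0=rng.uniform(-5, 5, n), tilt0=rng.uniform(-5, 5, n),
            twist0=rng.uniform(25, 40, n),
            beta_roll=np.full(n, 0.02), beta_tilt=np.full(n, 0.02),
            beta_twist=np.full(n, 0.02),
        )
        path = rbp_ground_state(chain)

        def rot(axis_idx, deg):
            t = np.deg2rad(deg)
            c, s = np.cos(t), np.sin(t)
            M = np.eye(4)
            if axis_idx == 0:
                M[:3, :3] = [[1, 0, 0], [0, c, -s], [0, s, c]]
            elif axis_idx == 1:
                M[:3, :3] = [[c, 0, s], [0, 1, 0], [-s, 0, c]]
            else:
                M[:3, :3] = [[c, -s, 0], [s, c, 0], [0, 0, 1]]
            return M

        T = np.eye(4)
        pts = [np.zeros(3)]
        for i in range(n):
            step = rot(0, chain.tilt0[i]) @ rot(1, chain.roll0[i]) @ rot(2, chain.twist0[i])
            step[:3, 3] = step[:3, :3] @ np.array([0, 0, chain.rise])
            T = T @ step
            pts.append(T[:3, 3].copy())
        np.testing.assert_allclose(path, np.array(pts), atol=1e-9)

    def test_minimum_at_satisfied_restraint(self):
        gamma, n = 6.0, 30
        chain = RigidBasePairChain(
            roll0=np.full(n, gamma), tilt0=np.zeros(n), twist0=np.zeros(n),
            beta_roll=np.full(n, 0.02), beta_tilt=np.full(n, 0.02),
            beta_twist=np.full(n, 0.02),
        )
        path = rbp_ground_state(chain)
        r_gs = float(np.linalg.norm(path[-1] - path[0]))
        res = rbp_restrained_minimize(chain, kappa=28.5, r0=r_gs, tol=1e-12, max_iter=5000)
        assert res.force == pytest.approx(0.0, abs=1e-3)
        assert res.energy == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(res.angles, chain.angles0(), atol=0.05)

    def test_descent_is_monotone_and_eq4_identity_holds(self):
        chain = RigidBasePairChain.straight(30)
        res = rbp_restrained_minimize(chain, kappa=28.5, r0=4.0)
        assert np.all(np.diff(res.energy_trace) <= 1e-10)
        assert res.force == pytest.approx(2 * 28.5 * (res.r - 4.0), rel=1e-12)

    def test_toy_chain_matches_multistart_optimizer(self, rng):
        from scipy.optimize import minimize
        from dnabow.bow import _end_to_end_and_grad

        n = 5
        chain = RigidBasePairChain(
            roll0=rng.uniform(-3, 3, n), tilt0=rng.uniform(-3, 3, n),
            twist0=np.full(n, 34.3),
            beta_roll=np.full(n, 0.02), beta_tilt=np.full(n, 0.02),
            beta_twist=np.full(n, 0.05),
        )
        kappa, r0 = 28.5, 0.8
        res = rbp_restrained_minimize(chain, kappa=kappa, r0=r0)

        betas, x0 = chain.betas(), chain.angles0()

        def energy(flat):
            ang = flat.reshape(n, 3)
            r, _ = _end_to_end_and_grad(chain, ang)
            return float(np.sum(betas * (ang - x0) ** 2)) + (kappa / KBT) * (r - r0) ** 2

        best = np.inf
        for k in range(10):
            start = x0.ravel() + rng.normal(0, 20, 3 * n)
            out = minimize(energy, start, method="Nelder-Mead",
                           options=dict(maxiter=4000, fatol=1e-10))
            best = min(best, out.fun)
        assert res.energy <= best * 1.01 + 1e-9


class TestRegisterScan:
    def small_chain(self):
        return RigidBasePairChain.straight(20)

    def test_straight_chain_register_symmetry(self):
        mean, sd, _ = register_scan(self.small_chain(), kappa=28.5, r0=3.0, n_registers=6)
        assert sd < 0.02 * abs(mean)

    def test_seeded_determinism(self):
        a = register_scan(self.small_chain(), kappa=28.5, r0=3.0, n_registers=4, seed=7)
        b = register_scan(self.small_chain(), kappa=28.5, r0=3.0, n_registers=4, seed=7)
        assert a[0] == b[0] and a[1] == b[1]
        np.testing.assert_array_equal(a[2], b[2])

    def test_uniform_vs_random_registers_agree(self):
        chain = self.small_chain()
        mean_u, sd_u, _ = register_scan(chain, kappa=28.5, r0=3.0, n_registers=6)
        mean_r, sd_r, _ = register_scan(chain, kappa=28.5, r0=3.0, n_registers=6, seed=3)
        spread = max(sd_u, sd_r, 1e-6)
        assert abs(mean_u - mean_r) < 2 * spread + 0.05 * abs(mean_u)
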