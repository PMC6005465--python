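"""Pair potentials and total-force assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import condensim as cs
from condensim.forces import total_forces, total_energy
from conftest import make_random_system

P = cs.SimParams(n_chains=1, N=60, M=3, Cr=1)


def bisect_cap_radius(eps=1.0, eps_cut=1000.0, lo=0.1, hi=1.0, tol=1e-14):
    """Independent oracle: solve 4 eps [(1/r)^12 - (1/r)^6 + 1/4] = eps_cut
    by bisection (the WCA energy is monotone decreasing on (0, 1))."""
    def u(r):
        sr6 = (1.0 / r) ** 6
        return 4.0 * eps * (sr6 * sr6 - sr6 + 0.25)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if u(mid) > eps_cut:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


class TestWCA:
    def test_contact_energy_is_one_kT(self):
        u, _ = cs.wca_energy_force(1.0, P)
        assert u == pytest.approx(1.0)

    def test_zero_at_and_beyond_cutoff(self):
        rc = 2.0 ** (1.0 / 6.0)
        for r in (rc, rc + 0.1, 3.0):
            assert cs.wca_energy_force(r, P) == (0.0, 0.0)

    def test_cap_engages_at_bisection_radius(self):
        r_cap = bisect_cap_radius()
        assert P.r_cap == pytest.approx(r_cap, rel=1e-12)
        u_in, f_in = cs.wca_energy_force(r_cap * (1 - 1e-9), P)
        assert u_in == 1000.0 and f_in == 0.0
        u_out, _ = cs.wca_energy_force(r_cap * (1 + 1e-9), P)
        assert u_out == pytest.approx(1000.0, rel=1e-6)
        assert u_out <= 1000.0

    def test_energy_never_exceeds_cap(self):
        for r in np.linspace(1e-3, 1.2, 500):
            u, _ = cs.wca_energy_force(r, P)
            assert u <= 1000.0 + 1e-9

    def test_linear_cap_mode_keeps_force(self):
        p = P.with_(cap_mode="linear")
        r = 0.9 * p.r_cap
        u, f = cs.wca_energy_force(r, p)
        _, f_cap = cs.wca_energy_force(p.r_cap * (1 + 1e-12), p)
        assert f == pytest.approx(f_cap, rel=1e-6)
        assert u > 1000.0

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            cs.wca_energy_force(0.0, P)
        with pytest.raises(ValueError):
            cs.wca_energy_force(-1.0, P)

    @given(st.floats(min_value=0.68, max_value=1.115))
    @settings(max_examples=60, deadline=None)
    def test_force_is_energy_gradient(self, r):
        h = 1e-7
        up, _ = cs.wca_energy_force(r + h, P)
        um, _ = cs.wca_energy_force(r - h, P)
        _, f = cs.wca_energy_force(r, P)
        assert f == pytest.approx(-(up - um) / (2 * h), rel=1e-5, abs=1e-6)


class TestSpring:
    def test_natural_length(self):
        assert cs.spring_energy_force(P.d_B, P) == (0.0, 0.0)

    def test_unit_stretch_energy(self):
        u, f = cs.spring_energy_force(P.d_B + 1.0, P)
        assert u == pytest.approx(500.0)      # eps_spr/2 with eps_spr = 1000
        assert f == pytest.approx(1000.0)

    def test_harmonic_symmetry(self):
        u_minus, _ = cs.spring_energy_force(P.d_B - 0.5, P)
        u_plus, _ = cs.spring_energy_force(P.d_B + 0.5, P)
        assert u_minus == pytest.approx(u_plus)


class TestLoopHolding:
    def test_coincident_is_zero(self):
        anchors = np.zeros((2, 3))
        u, f_anchor, f_cond = cs.loop_energy_force(np.zeros(3), anchors, 1.0)
        assert u == 0.0
        assert np.all(f_anchor == 0.0) and np.all(f_cond == 0.0)

    def test_unit_distances(self):
        anchors = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        u, _, f_cond = cs.loop_energy_force(np.zeros(3), anchors, 1.0)
        assert u == pytest.approx(1.0)        # (1/2)(1 + 1)
        assert np.allclose(f_cond, 0.0)       # symmetric pull cancels

    def test_linearity_in_strength(self):
        rng = np.random.default_rng(0)
        c, a = rng.normal(size=3), rng.normal(size=(2, 3))
        u1, fa1, fc1 = cs.loop_energy_force(c, a, 1.3)
        u2, fa2, fc2 = cs.loop_energy_force(c, a, 2.6)
        assert u2 == pytest.approx(2 * u1)
        assert np.allclose(fa2, 2 * fa1) and np.allclose(fc2, 2 * fc1)

    def test_action_reaction(self):
        rng = np.random.default_rng(1)
        c, a = rng.normal(size=3), rng.normal(size=(2, 3))
        _, f_anchor, f_cond = cs.loop_energy_force(c, a, 0.7)
        assert np.allclose(f_cond + f_anchor.sum(axis=0), 0.0)


class TestAttraction:
    def test_zero_at_threshold_and_beyond(self):
        assert cs.attraction_energy_force(2.0, 1.0, 2.0) == (0.0, 0.0)
        assert cs.attraction_energy_force(3.0, 1.0, 2.0) == (0.0, 0.0)

    def test_contact_energy(self):
        u, f = cs.attraction_energy_force(0.0, 1.0, 2.0)
        assert u == pytest.approx(-4.0)       # -F_cond * Delta^2

    def test_force_is_attractive_gradient(self):
        for r in (0.3, 1.0, 1.7):
            h = 1e-7
            up, _ = cs.attraction_energy_force(r + h, 1.5, 2.0)
            um, _ = cs.attraction_energy_force(r - h, 1.5, 2.0)
            _, f = cs.attraction_energy_force(r, 1.5, 2.0)
            # reported magnitude pulls inward: equals +dU/dr here
            assert f == pytest.approx((up - um) / (2 * h), rel=1e-5)
            assert f > 0.0


class TestTotalForces:
    def test_isolated_pair_beyond_cutoffs(self, rng):
        state, topo = make_random_system(2, 0, rng, with_springs=False)
        state.mon_pos[:] = [[0, 0, 0], [3, 0, 0]]
        p = cs.SimParams(n_chains=1, N=2, M=1, Cr=0)
        f_mon, _ = total_forces(state, topo, p)
        assert np.all(f_mon == 0.0)

    @pytest.mark.parametrize("method", ["cell", "brute"])
    def test_newtons_third_law(self, rng, method):
        state, topo = make_random_system(30, 6, rng, n_chains=2)
        p = cs.SimParams(n_chains=2, N=15, M=3, Cr=0, Delta=3.0)
        f_mon, f_cond = total_forces(state, topo, p, method=method)
        total = f_mon.sum(axis=0) + f_cond.sum(axis=0)
        assert np.allclose(total, 0.0, atol=1e-9)

    def test_forces_match_finite_differences(self, rng):
        # keep pair distances away from the cap/cutoff kinks so central
        # differences of the energy are accurate
        p = cs.SimParams(n_chains=1, N=30, M=3, Cr=0, Delta=2.5,
                         F_cond=0.8, F_loop=1.3)
        while True:
            state, topo = make_random_system(30, 3, rng, box=3.0)
            d = state.mon_pos[:, None, :] - state.mon_pos[None, :, :]
            r = np.sqrt((d ** 2).sum(-1))[np.triu_indices(30, 1)]
            if (np.abs(r - p.r_cap).min() > 0.02
                    and np.abs(r - p.r_cut).min() > 0.02
                    and r.min() > p.r_cap + 0.02):
                break
        f_mon, f_cond = total_forces(state, topo, p)
        h = 1e-6
        for arr, f in ((state.mon_pos, f_mon), (state.cond_pos, f_cond)):
            for i in range(arr.shape[0]):
                for k in range(3):
                    orig = arr[i, k]
                    arr[i, k] = orig + h
                    up = total_energy(state, topo, p)
                    arr[i, k] = orig - h
                    um = total_energy(state, topo, p)
                    arr[i, k] = orig
                    fd = -(up - um) / (2 * h)
                    assert f[i, k] == pytest.approx(fd, rel=1e-5, abs=1e-4)

    def test_cell_list_matches_brute_force(self, rng):
        p = cs.SimParams(n_chains=2, N=100, M=10, Cr=0, Delta=2.0)
        state, topo = make_random_system(200, 20, rng, box=5.0, n_chains=2)
        f_cell, g_cell = total_forces(state, topo, p, method="cell")
        f_brut, g_brut = total_forces(state, topo, p, method="brute")
        scale = max(np.abs(f_brut).max(), 1.0)
        assert np.allclose(f_cell, f_brut, rtol=0, atol=1e-12 * scale)
        assert np.allclose(g_cell, g_brut, rtol=0,
                           atol=1e-12 * max(np.abs(g_brut).max(), 1.0))

    def test_attraction_locality(self, rng):
        """Moving a condensin that is farther than Delta from all others
        must not change any attraction force."""
        p = cs.SimParams(n_chains=1, N=10, M=5, Cr=0, Delta=1.0, F_loop=0.0)
        state, topo = make_random_system(10, 5, rng, box=0.1)
        topo.anchors = np.zeros((0, 2), dtype=np.int64)
        state.cond_pos = np.array(
            [[0, 0, 0], [0.5, 0, 0], [0, 0.5, 0], [10, 10, 10], [20, 0, 0]],
            dtype=float)
        _, f0 = total_forces(state, topo, p)
        state.cond_pos[3] += [1.0, -2.0, 0.5]   # still isolated
        _, f1 = total_forces(state, topo, p)
        assert np.allclose(f0[:3], f1[:3])
        assert np.all(f1[3] == 0.0)

    def test_size_mismatch_rejected(self, rng):
        state, topo = make_random_system(30, 3, rng)
        p = cs.SimParams(n_chains=1, N=60, M=3, Cr=1)
        with pytest.raises(ValueError):
            total_forces(state, topo, p)

    def test_coincident_monomers_survive(self):
        """Coincident particles return capped energy with zero force."""
        state, topo = make_random_system(
            2, 0, np.random.default_rng(0), with_springs=False)
        state.mon_pos[:] = 0.0
        p = cs.SimParams(n_chains=1, N=2, M=1, Cr=0)
        f_mon, _ = total_forces(state, topo, p)
        assert np.all(np.isfinite(f_mon)) and np.all(f_mon == 0.0)
        assert total_energy(state, topo, p) == pytest.approx(1000.0)
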