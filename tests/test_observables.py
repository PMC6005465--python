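"""Shape and segregation order parameters."""

import numpy as np
import pytest

import condensim as cs
from condensim.observables import (
    DegenerateConfigurationError, axis_distances, first_crossing_time,
    loop_spheres, trans_decay_time,
)


def random_rotation(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class TestGyrationTensor:
    def test_single_point(self):
        G, lam = cs.gyration_tensor(np.zeros((1, 3)))
        assert np.all(G == 0.0) and np.all(lam == 0.0)
        assert cs.radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_cube_corners(self):
        """Eight corners at +-1: G is the identity, Rg = sqrt(3)."""
        corners = np.array([[sx, sy, sz] for sx in (-1, 1)
                            for sy in (-1, 1) for sz in (-1, 1)], dtype=float)
        G, lam = cs.gyration_tensor(corners)
        assert np.allclose(G, np.eye(3))
        assert np.allclose(lam, 1.0)
        assert cs.radius_of_gyration(corners) == pytest.approx(np.sqrt(3))

    def test_rotation_invariance(self):
        rng = np.random.default_rng(2)
        pos = rng.standard_normal((40, 3))
        _, lam = cs.gyration_tensor(pos)
        _, lam_rot = cs.gyration_tensor(pos @ random_rotation(rng).T)
        assert np.allclose(lam, lam_rot, atol=1e-10)

    def test_rg_equals_rms_distance_from_com(self):
        rng = np.random.default_rng(3)
        pos = rng.standard_normal((100, 3)) * [3, 1, 0.2]
        rg = cs.radius_of_gyration(pos)
        rms = np.sqrt(np.mean(np.sum((pos - pos.mean(0)) ** 2, axis=1)))
        assert rg == pytest.approx(rms, abs=1e-10)


class TestAsphericity:
    def test_isotropic_cloud_is_zero(self):
        """lambda1 = lambda2 = lambda3 gives a spherical shape, A = 0."""
        corners = np.array([[sx, sy, sz] for sx in (-1, 1)
                            for sy in (-1, 1) for sz in (-1, 1)], dtype=float)
        assert cs.asphericity(corners) == pytest.approx(0.0, abs=1e-12)

    def test_collinear_is_one(self):
        pos = np.outer(np.arange(10.0), [1.0, 2.0, -1.0])
        assert cs.asphericity(pos) == pytest.approx(1.0)

    def test_half_for_4_1_1_eigenvalues(self):
        """lambda^2 = (4, 1, 1) -> (4 - 1) / 6 = 0.5; realized by a
        point set with per-axis variances (4, 1, 1)."""
        pos = np.array([[2.0, 0, 0], [-2.0, 0, 0], [0, 1.0, 0],
                        [0, -1.0, 0], [0, 0, 1.0], [0, 0, -1.0]])
        # variances: x: 8/6, y: 2/6, z: 2/6 -> ratios (4, 1, 1)
        assert cs.asphericity(pos) == pytest.approx(0.5)

    def test_coincident_points_signal_degeneracy(self):
        with pytest.raises(DegenerateConfigurationError):
            cs.asphericity(np.ones((5, 3)))

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pos = rng.standard_normal((15, 3)) * rng.uniform(0.1, 5, 3)
            assert 0.0 <= cs.asphericity(pos) <= 1.0


class TestLoopSpheres:
    def test_coincident_loop_has_zero_radius(self):
        pos = np.zeros((10, 3))
        centers, radii = loop_spheres(pos, L=5)
        assert np.all(radii == 0.0)

    def test_ring_loop(self):
        theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        rho = 2.5
        pos = np.stack([rho * np.cos(theta), rho * np.sin(theta),
                        np.zeros(12)], axis=1)
        centers, radii = loop_spheres(pos, L=12)
        assert np.allclose(centers[0], 0.0, atol=1e-12)
        assert radii[0] == pytest.approx(rho)

    def test_translation_moves_centers_keeps_radii(self):
        rng = np.random.default_rng(1)
        pos = rng.standard_normal((20, 3))
        c0, r0 = loop_spheres(pos, L=10)
        c1, r1 = loop_spheres(pos + [5, -3, 2], L=10)
        assert np.allclose(c1 - c0, [5, -3, 2])
        assert np.allclose(r0, r1)


class TestOverlap:
    def test_identical_chains_overlap_one(self):
        rng = np.random.default_rng(4)
        chain = rng.standard_normal((20, 3))
        assert cs.overlap(chain, chain.copy(), L=10) == pytest.approx(1.0)

    def test_distant_chains_overlap_zero(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((20, 3))
        b = rng.standard_normal((20, 3)) + 1e3
        assert cs.overlap(a, b, L=10) == 0.0

    def test_matches_brute_force_membership(self):
        """Two-loop toy chains checked against direct all-monomer /
        all-sphere membership counting."""
        rng = np.random.default_rng(6)
        a = rng.standard_normal((10, 3)) * 1.5
        b = rng.standard_normal((10, 3)) * 1.5 + [1.0, 0.5, 0.0]
        L = 5

        def region_count(points, chain):
            hits = 0
            for pnt in points:
                inside = False
                for i in range(2):
                    loop = chain[i * L:(i + 1) * L]
                    c = loop.mean(axis=0)
                    r = max(np.linalg.norm(loop - c, axis=1))
                    if np.linalg.norm(pnt - c) <= r:
                        inside = True
                hits += inside
            return hits / len(points)

        expected = 0.5 * (region_count(a, b) + region_count(b, a))
        assert cs.overlap(a, b, L) == pytest.approx(expected)
        assert cs.overlap(a, b, L, symmetrize=False) == pytest.approx(
            region_count(a, b))


class TestAttractionFractions:
    def test_all_isolated(self):
        pos = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [10, 10, 0.0]])
        chain = np.array([0, 0, 1, 1])
        assert cs.attraction_fractions(pos, chain, Delta=1.0) == (0.0, 0.0)

    def test_interleaved_trans_is_one(self):
        pos = np.array([[0, 0, 0], [0.5, 0, 0], [2, 0, 0], [2.5, 0, 0.0]])
        chain = np.array([0, 1, 0, 1])
        trans, _ = cs.attraction_fractions(pos, chain, Delta=0.8)
        assert trans == 1.0

    def test_four_condensin_toy_half_trans(self):
        """One trans pair within Delta out of four condensins -> 0.5."""
        pos = np.array([[0, 0, 0], [5, 0, 0], [0.5, 0, 0], [9, 9, 9.0]])
        chain = np.array([0, 0, 1, 1])
        trans, cis = cs.attraction_fractions(pos, chain, Delta=1.0)
        assert trans == pytest.approx(0.5)
        assert cis == 0.0

    def test_counts_toward_both(self):
        # pairwise distances: 0-1 cis 0.4, 0-2 trans 0.4, 1-2 trans 0.57
        pos = np.array([[0, 0, 0], [0.4, 0, 0], [0, 0.4, 0.0]])
        chain = np.array([0, 0, 1])
        trans, cis = cs.attraction_fractions(pos, chain, Delta=1.0)
        assert trans == pytest.approx(1.0)    # every condensin has a trans partner
        assert cis == pytest.approx(2 / 3)    # the two chain-0 condensins


class TestSegregationMetrics:
    def test_linear_ramp_crossing(self):
        """Overlap falling linearly through 0.2 at t = 1000 gives speed
        1e-3."""
        t = np.linspace(0, 2000, 21)
        overlap = 1.0 - t * 0.0008              # hits 0.2 at t = 1000
        m = cs.segregation_metrics(t, overlap)
        assert m["segregation_time"] == pytest.approx(1000.0)
        assert m["segregation_speed"] == pytest.approx(1.0e-3)
        assert m["segregation_censored"] == 0.0

    def test_censored_when_never_crossing(self):
        t = np.linspace(0, 100, 11)
        m = cs.segregation_metrics(t, np.full(11, 0.6))
        assert np.isnan(m["segregation_time"])
        assert m["segregation_speed"] == 0.0
        assert m["segregation_censored"] == 1.0

    def test_crossing_stable_under_resampling(self):
        rng = np.random.default_rng(8)
        t = np.linspace(0, 500, 26)
        v = np.clip(1.0 - (t / 400.0) ** 1.5, 0, 1)
        t2 = np.linspace(0, 500, 51)
        v2 = np.interp(t2, t, v)
        c1 = first_crossing_time(t, v, 0.2)
        c2 = first_crossing_time(t2, v2, 0.2)
        assert c1 == pytest.approx(c2, rel=1e-9)

    def test_trans_decay_requires_sustained_zero(self):
        t = np.arange(6.0)
        flicker = np.array([0.4, 0.0, 0.3, 0.0, 0.0, 0.0])
        assert trans_decay_time(t, flicker) == 3.0
        assert trans_decay_time(t, np.array([0.4, 0.3, 0.2, 0.1, 0.1, 0.05])) is None

    def test_unsorted_series_rejected(self):
        with pytest.raises(ValueError):
            first_crossing_time(np.array([0.0, 2.0, 1.0]),
                                np.array([1.0, 0.5, 0.1]), 0.2)


class TestAxisDensity:
    def test_straight_line_collapses_to_origin(self):
        pos = np.outer(np.arange(20.0), [1.0, 0, 0])
        profile = cs.axis_density(pos, interval=5, bin_width=0.25)
        assert profile["density"].iloc[0] == 1.0
        assert profile["density"].iloc[1:].sum() == 0.0

    def test_cylinder_mass_near_radius(self):
        """Condensins on a helix of radius rho around a straight axis:
        distance mass concentrates near rho (axis endpoints on the axis)."""
        n = 40
        z = np.linspace(0, 40, n)
        rho = 1.5
        phase = np.linspace(0, 12 * np.pi, n)
        pos = np.stack([rho * np.cos(phase), rho * np.sin(phase), z], axis=1)
        # put segment endpoints on the axis so segments track the axis
        for i in range(0, n, 5):
            pos[i] = [0, 0, z[i]]
            pos[min(i + 4, n - 1)] = [0, 0, z[min(i + 4, n - 1)]]
        d = axis_distances(pos, interval=5)
        interior = d[d > 1e-9]
        assert np.all(np.abs(interior - rho) < 0.35)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(9)
        pos = rng.standard_normal((20, 3)) * [1, 1, 6]
        d0 = axis_distances(pos, interval=5)
        moved = pos @ random_rotation(rng).T + [4.0, -2.0, 7.0]
        d1 = axis_distances(moved, interval=5)
        assert np.allclose(d0, d1, atol=1e-9)

    def test_too_few_segments_rejected(self):
        with pytest.raises(ValueError, match="segments"):
            axis_distances(np.zeros((5, 3)), interval=5)
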