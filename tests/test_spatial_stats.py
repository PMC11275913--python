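"""Ripley's-K ratio machinery, histogram peaks and the rank-sum test."""

import itertools

import numpy as np
import pytest

from cotransmap import (
    KConfig,
    KCurve,
    PlacementConfig,
    ThomasParams,
    histogram_peak,
    k_ratio_curve,
    mann_whitney,
    max_ratio_by_interval,
    mean_pair_count_curve,
    place_particles,
    sample_surface_points,
)


class TestPairCounts:
    def test_matches_exhaustive_double_loop(self, rng):
        pts = rng.uniform(0, 2000, (50, 3))
        radii = np.array([10.0, 50.0, 100.0, 150.0])
        ours = mean_pair_count_curve(pts, radii)
        for r, k in zip(radii, ours):
            count = sum(
                np.linalg.norm(pts[i] - pts[j]) <= r * 10.0
                for i in range(50)
                for j in range(i + 1, 50)
            )
            assert np.isclose(k, 2 * count / 50)

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            mean_pair_count_curve(np.zeros((1, 3)), np.array([1.0]))

    def test_invariant_under_rigid_transform(self, rng):
        from scipy.spatial.transform import Rotation

        pts = rng.uniform(0, 2000, (40, 3))
        R = Rotation.random(random_state=np.random.RandomState(5)).as_matrix()
        moved = pts @ R.T + np.array([100.0, -50.0, 30.0])
        radii = np.linspace(27, 166, 20)
        assert np.allclose(
            mean_pair_count_curve(pts, radii), mean_pair_count_curve(moved, radii)
        )


class TestKRatio:
    def test_csr_points_give_ratio_near_one(self, sphere_scene):
        omm = sphere_scene[0]
        pts, _ = sample_surface_points(omm, 500, np.random.default_rng(77))
        curve = k_ratio_curve(pts, omm, KConfig(n_null_reps=20, rng_seed=78))
        assert 0.9 <= np.nanmean(curve.ratio) <= 1.1

    def test_coincident_points_blow_up_smallest_radius(self, sphere_scene):
        omm = sphere_scene[0]
        pts = np.tile(omm.centroids[0], (30, 1))
        curve = k_ratio_curve(pts, omm, KConfig(n_null_reps=5, rng_seed=1))
        assert curve.ratio[0] > 10

    def test_shell_null_calibrates_hovering_pattern(self, sphere_scene):
        """Points hovering uniformly off the membrane read as random under
        the shell null but as depleted-at-short-range under the surface
        null (the shell spreads pairs into the extra dimension)."""
        omm = sphere_scene[0]
        rng = np.random.default_rng(9)
        pts, ids = sample_surface_points(omm, 300, rng)
        pts = pts + rng.uniform(-150, 150, 300)[:, None] * omm.normals[ids]
        shell = k_ratio_curve(
            pts, omm,
            KConfig(n_null_reps=10, null_model="shell", shell_thickness=300.0,
                    rng_seed=10),
        )
        surface = k_ratio_curve(pts, omm, KConfig(n_null_reps=10, rng_seed=10))
        assert abs(np.nanmean(shell.ratio) - 1.0) < 0.1
        assert np.nanmean(surface.ratio[:20]) < np.nanmean(shell.ratio[:20])

    def test_deterministic_under_seed(self, sphere_scene):
        omm = sphere_scene[0]
        pts, _ = sample_surface_points(omm, 50, np.random.default_rng(3))
        c1 = k_ratio_curve(pts, omm, KConfig(n_null_reps=5, rng_seed=42))
        c2 = k_ratio_curve(pts, omm, KConfig(n_null_reps=5, rng_seed=42))
        assert np.array_equal(c1.k_csr, c2.k_csr)

    def test_thomas_more_clustered_than_csr_at_30_40nm(self, sphere_scene):
        omm = sphere_scene[0]
        t, _ = place_particles(
            omm, PlacementConfig(cluster=ThomasParams(10, 10, 15.0), rng_seed=6)
        )
        csr_pts, _ = sample_surface_points(omm, 100, np.random.default_rng(7))
        kcfg = KConfig(n_null_reps=10, rng_seed=8)
        iv_t = max_ratio_by_interval(k_ratio_curve(t.positions, omm, kcfg))
        iv_c = max_ratio_by_interval(k_ratio_curve(csr_pts, omm, kcfg))
        assert iv_t[(30.0, 40.0)] > iv_c[(30.0, 40.0)]


class TestIntervalMaxima:
    def _curve(self, radii, ratio):
        k_csr = np.ones_like(radii, dtype=float)
        return KCurve(radii=radii, k_obs=np.asarray(ratio, float), k_csr=k_csr,
                      n_points=10, n_null_reps=1)

    def test_constant_ratio(self):
        radii = np.arange(27.0, 167.0)
        curve = self._curve(radii, np.ones_like(radii))
        maxima = max_ratio_by_interval(curve, 10.0)
        assert all(np.isclose(v, 1.0) for v in maxima.values())

    def test_spike_lands_in_its_interval(self):
        radii = np.arange(27.0, 167.0)
        ratio = np.ones_like(radii)
        ratio[radii == 35.0] = 7.5
        maxima = max_ratio_by_interval(self._curve(radii, ratio), 10.0)
        assert maxima[(30.0, 40.0)] == 7.5
        assert maxima[(40.0, 50.0)] == 1.0

    def test_matches_exhaustive_scan(self, rng):
        radii = np.arange(27.0, 167.0)
        ratio = rng.uniform(0.5, 3.0, radii.shape)
        maxima = max_ratio_by_interval(self._curve(radii, ratio), 10.0)
        for (a, b), v in maxima.items():
            sel = (radii >= a) & (radii < b)
            assert np.isclose(v, ratio[sel].max())

    def test_empty_interval_is_missing(self):
        radii = np.array([27.0, 28.0, 55.0])
        maxima = max_ratio_by_interval(self._curve(radii, [1.0, 1.0, 2.0]), 10.0)
        assert np.isnan(maxima[(30.0, 40.0)])
        assert maxima[(50.0, 60.0)] == 2.0


class TestHistogramPeak:
    def test_degenerate_range(self):
        assert histogram_peak([120.0] * 50) == 120.0

    def test_peak_resists_outliers(self, rng):
        vals = np.concatenate([rng.normal(100, 2, 1000), np.full(10, 300.0)])
        peak = histogram_peak(vals)
        # oracle: direct mode of the binned counts
        counts, edges = np.histogram(vals, bins=100, range=(vals.min(), vals.max()))
        expected = 0.5 * (edges[counts.argmax()] + edges[counts.argmax() + 1])
        assert peak == expected
        assert abs(peak - 100.0) < 5.0

    def test_tie_breaks_to_lower_bin(self):
        # two bins of equal count at the extremes of [0, 100]
        vals = np.array([0.0, 0.1, 99.9, 100.0])
        peak = histogram_peak(vals, n_bins=100)
        assert peak < 50.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            histogram_peak([])


class TestMannWhitney:
    def test_exact_p_by_enumeration(self):
        """{1,2,3} vs {4,5,6}: U = 0; exhaustive enumeration of all
        C(6,3) = 20 equally likely rank splits gives two-sided p = 0.1."""
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        # enumeration oracle
        pooled = [1, 2, 3, 4, 5, 6]
        obs_u = 0
        count_extreme = 0
        splits = list(itertools.combinations(range(6), 3))
        for idx in splits:
            a = [pooled[i] for i in idx]
            b = [pooled[i] for i in range(6) if i not in idx]
            ua = sum(x > y for x in a for y in b)
            if min(ua, 9 - ua) <= min(obs_u, 9 - obs_u):
                count_extreme += 1
        expected = count_extreme / len(splits)
        assert np.isclose(p, expected) and np.isclose(p, 0.1)

    def test_identical_groups_p_near_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p > 0.9

    def test_agrees_with_permutation_oracle(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 12)
        _, p = mann_whitney(a, b)
        # permutation oracle on the U statistic
        pooled = np.concatenate([a, b])
        obs = sum(x > y for x in a for y in b) + 0.5 * sum(x == y for x in a for y in b)
        n_perm = 3000
        dev_obs = abs(obs - len(a) * len(b) / 2)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            pa, pb = perm[:12], perm[12:]
            u = sum(x > y for x in pa for y in pb) + 0.5 * sum(x == y for x in pa for y in pb)
            if abs(u - 72) >= dev_obs - 1e-12:
                hits += 1
        p_perm = hits / n_perm
        assert abs(p - p_perm) < 0.05  # within Monte-Carlo error

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])
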