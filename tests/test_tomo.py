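"""Domain segmentation, effective diameters, k-NN, g(r) coordination and
skew-normal size fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mesochrom.tomo import (
    LACVolume,
    domain_rdf_and_zc,
    effective_diameter,
    fit_skew_normal,
    hmd_threshold,
    knn_distances,
    lac_statistics,
    segment_domains,
)


def sphere_volume(shape, center_nm, radius_nm, voxel=13.0, inside=0.25,
                  outside=0.12):
    zz, yy, xx = np.meshgrid(
        *[(np.arange(s) + 0.5) * voxel for s in shape], indexing="ij")
    lac = np.full(shape, outside)
    for c, r in zip(center_nm, [radius_nm] * 1):
        pass
    d2 = ((zz - center_nm[0]) ** 2 + (yy - center_nm[1]) ** 2
          + (xx - center_nm[2]) ** 2)
    lac[d2 <= radius_nm**2] = inside
    return LACVolume(lac, voxel, np.ones(shape, dtype=np.int16))


class TestThreshold:
    def test_unit_range(self):
        assert hmd_threshold(np.array([0.0, 1.0])) == pytest.approx(0.6)

    def test_reported_lac_range(self):
        # the 0.1-0.25 1/um heterochromatin range thresholds at 0.19
        assert hmd_threshold(np.array([0.10, 0.18, 0.25])) == pytest.approx(
            0.19)

    def test_constant_region_warns(self):
        with pytest.warns(RuntimeWarning):
            t = hmd_threshold(np.full(10, 0.2))
        assert t == 0.2

    def test_empty_region_errors(self):
        with pytest.raises(ValueError):
            hmd_threshold(np.array([]))


class TestEffectiveDiameter:
    def test_no_missing_wedge(self):
        f, _ = effective_diameter(1.0, 1.3, 1.3)
        assert f == 1.0

    def test_unit_sphere_inversion(self):
        _, d = effective_diameter(np.pi / 6, 1.0, 1.0)
        assert d == pytest.approx(1.0)

    def test_80nm_sphere_inversion(self):
        _, d = effective_diameter(np.pi / 6 * 80**3, 1.0, 1.0)
        assert d == pytest.approx(80.0)

    def test_monotone_in_volume_and_fmw(self):
        _, d1 = effective_diameter(1e5, 1.0, 1.0)
        _, d2 = effective_diameter(2e5, 1.0, 1.0)
        _, d3 = effective_diameter(1e5, 1.5, 1.0)
        assert d2 > d1 and d3 > d1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            effective_diameter(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            effective_diameter(1.0, 1.0, 0.0)


class TestSegmentation:
    def test_single_sphere_recovered(self):
        vol = sphere_volume((32, 32, 32), (208, 208, 208), 40.0)
        labels, table = segment_domains(vol)
        assert len(table) == 1
        assert table.d_eff_nm.iloc[0] == pytest.approx(80.0, abs=13.0)

    def test_fused_spheres_split_by_watershed(self):
        voxel = 13.0
        shape = (40, 40, 64)
        zz, yy, xx = np.meshgrid(
            *[(np.arange(s) + 0.5) * voxel for s in shape], indexing="ij")
        lac = np.full(shape, 0.12)
        c1 = (260, 260, 300)
        c2 = (260, 260, 510)
        r = 80.0
        for c in (c1, c2):
            d2 = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
            lac[d2 <= r**2] = 0.25
        # thin cylindrical neck (radius << sphere radius) along x
        neck = (np.abs(zz - 260) < 20) & (np.abs(yy - 260) < 20) \
            & (xx > c1[2]) & (xx < c2[2])
        lac[neck] = 0.25
        vol = LACVolume(lac, voxel, np.ones(shape, np.int16))
        _, table = segment_domains(vol)
        assert len(table) == 2

    def test_all_background_empty_table(self):
        vol = LACVolume(np.full((16, 16, 16), 0.1), 13.0,
                        np.ones((16, 16, 16), np.int16))
        labels, table = segment_domains(vol, threshold=0.5)
        assert len(table) == 0
        assert labels.max() == 0

    def test_labels_partition_foreground(self):
        vol = sphere_volume((32, 32, 32), (208, 208, 208), 60.0)
        thr = hmd_threshold(vol.data[vol.mask == 1])
        labels, table = segment_domains(vol, threshold=thr)
        fg = vol.data >= thr
        # every counted voxel belongs to exactly one domain; domains below
        # the minimum size are dropped from both labels and table
        assert int((labels > 0).sum()) == int(table.n_voxels.sum())
        assert (labels[~fg] == 0).all()
        assert table.volume_nm3.sum() == pytest.approx(
            (labels > 0).sum() * 13.0**3)


class TestKNN:
    def test_collinear_points(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [3.0, 0, 0]])
        dist, pooled = knn_distances(pts, k_max=1)
        assert sorted(dist[:, 0].tolist()) == [1.0, 1.0, 2.0]

    def test_matches_brute_force(self, rng):
        pts = rng.uniform(0, 100, size=(100, 3))
        dist, _ = knn_distances(pts, k_max=10)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        brute = np.sort(d, axis=1)[:, :10]
        assert np.allclose(dist, brute)
        assert np.all(np.diff(dist, axis=1) >= 0)

    def test_truncation_warns(self, rng):
        pts = rng.uniform(0, 10, size=(5, 3))
        with pytest.warns(RuntimeWarning):
            dist, _ = knn_distances(pts, k_max=10)
        assert dist.shape == (5, 4)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            knn_distances(np.zeros((1, 3)))


class TestDomainRDFCoordination:
    def test_fcc_coordination_is_12(self):
        # FCC lattice: 12 nearest neighbours; quadrature of the
        # first g(r) peak must agree with the brute-force count within 5%
        a = 100.0  # cubic lattice constant, nm
        reps = 9
        base = np.array([[0, 0, 0], [0, 0.5, 0.5], [0.5, 0, 0.5],
                         [0.5, 0.5, 0]])
        pts = np.vstack([
            (base + [i, j, k]) * a
            for i in range(reps) for j in range(reps) for k in range(reps)
        ])
        pts = pts - pts.mean(axis=0)
        r_cut = 4.2 * a  # spherical sample; region radius matched to cut
        pts = pts[np.linalg.norm(pts, axis=1) <= r_cut]
        nn = a / np.sqrt(2)
        # brute-force oracle: neighbours within 1.3 * nn distance
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        core = np.linalg.norm(pts, axis=1) <= 2.0 * a
        z_brute = (d[core] <= 1.3 * nn).sum(axis=1).mean()
        assert z_brute == pytest.approx(12.0, abs=0.01)

        res = domain_rdf_and_zc(pts, region_radius_nm=r_cut,
                                mean_domain_radius_nm=0.3 * nn,
                                bin_width_nm=6.0)
        assert res.z == pytest.approx(12.0, rel=0.05)

    def test_ideal_gas_closed_form(self):
        # Poisson points: z must match (4/3) pi rho (r2^3 - r1^3)
        rng = np.random.default_rng(20240917)  # local: order-independent
        r_cav = 500.0
        n = 600
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts *= r_cav * rng.uniform(size=(n, 1)) ** (1 / 3)
        r1 = 20.0
        bw = 13.0
        res = domain_rdf_and_zc(pts, region_radius_nm=r_cav,
                                mean_domain_radius_nm=r1, bin_width_nm=bw)
        assert res.z is not None and res.r2_nm is not None
        # closed form over the same bin support the quadrature used
        xs = res.bins_nm
        sel = (xs >= r1) & (xs <= res.r2_nm)
        lo, hi = xs[sel].min() - bw / 2, xs[sel].max() + bw / 2
        closed = 4 / 3 * np.pi * res.rho * (hi**3 - lo**3)
        assert res.z == pytest.approx(closed, rel=0.35)

    def test_too_few_centroids(self):
        with pytest.raises(ValueError):
            domain_rdf_and_zc(np.zeros((5, 3)))


class TestSkewNormalFit:
    def test_normal_recovers_zero_alpha(self, rng):
        x = rng.normal(10, 2, size=5000)
        fit = fit_skew_normal(x, n_boot=60, seed=1)
        assert fit.alpha_ci[0] <= 0.0 <= fit.alpha_ci[1] or abs(
            fit.alpha) < 0.5

    def test_skewed_recovery(self, rng):
        x = sps.skewnorm.rvs(4.0, loc=50, scale=30, size=5000,
                             random_state=rng)
        fit = fit_skew_normal(x, n_boot=0)
        assert fit.alpha == pytest.approx(4.0, rel=0.25)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            fit_skew_normal(np.full(100, 3.0))

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            fit_skew_normal(np.arange(10.0))


class TestLACStatistics:
    def test_constant_region(self):
        vol = LACVolume(np.full((8, 8, 8), 0.17), 13.0,
                        np.ones((8, 8, 8), np.int16))
        s = lac_statistics(vol)
        assert s[1]["min"] == s[1]["max"] == pytest.approx(0.17)
        assert s[1]["mean"] == pytest.approx(0.17)

    def test_two_labels_independent(self):
        data = np.zeros((8, 8, 8))
        labels = np.zeros((8, 8, 8), dtype=np.int16)
        data[:4] = 0.1
        labels[:4] = 1
        data[4:] = 0.3
        labels[4:] = 2
        s = lac_statistics(LACVolume(data, 13.0, labels))
        assert s[1]["mean"] == pytest.approx(0.1)
        assert s[2]["mean"] == pytest.approx(0.3)

    def test_phantom_ranges_recovered(self):
        from mesochrom.synth import PhantomConfig, generate_phantom

        vol, _ = generate_phantom(
            PhantomConfig(shape=(40, 56, 56), n_domains=25), seed=3)
        s = lac_statistics(vol)
        hc = s[1]
        assert 0.10 <= hc["min"] <= 0.16
        assert 0.20 <= hc["max"] <= 0.28
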