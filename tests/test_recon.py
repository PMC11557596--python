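"""Forward projection, SIRT reconstruction and FSC resolution."""

import numpy as np
import pytest

from mesochrom.recon import (
    SIRTDivergence,
    TiltSeries,
    corrected_fsc,
    default_angles,
    fsc_curve,
    fsc_resolution,
    project_tilt_series,
    projector_matrix,
    sirt_reconstruct,
)
from mesochrom.tomo.volume import LACVolume


def sphere_phantom(n=32, radius_vox=8.0, lac=0.2, ny=None):
    ny = ny or n
    z, y, x = np.meshgrid(np.arange(n) - (n - 1) / 2,
                          np.arange(ny) - (ny - 1) / 2,
                          np.arange(n) - (n - 1) / 2, indexing="ij")
    vol = np.zeros((n, ny, n))
    vol[(z**2 + y**2 + x**2) <= radius_vox**2] = lac
    return LACVolume(vol, 13.0)


class TestProjection:
    def test_uniform_sphere_chord_lengths(self):
        # at 0 degrees the projection equals LAC x chord length
        vol = sphere_phantom(n=48, radius_vox=12.0, lac=0.3, ny=48)
        ts = project_tilt_series(vol, np.array([0.0]))
        proj = ts.sinogram[0]  # (y, x)
        yy, xx = np.meshgrid(np.arange(48) - 23.5, np.arange(48) - 23.5,
                             indexing="ij")
        r2 = yy**2 + xx**2
        chord_vox = 2.0 * np.sqrt(np.maximum(12.0**2 - r2, 0.0))
        expected = 0.3 * chord_vox * 13e-3
        # interpolation smooths the rim; compare away from the edge
        interior = r2 <= 9.0**2
        assert np.abs(proj[interior] - expected[interior]).max() < 0.05 * \
            expected[interior].max()

    def test_zero_volume_projects_to_zero(self):
        vol = LACVolume(np.zeros((16, 16, 16)), 13.0)
        ts = project_tilt_series(vol, np.array([-30.0, 0.0, 30.0]))
        assert np.allclose(ts.sinogram, 0.0)
        assert np.allclose(ts.intensity, ts.i0)

    def test_mirror_symmetry(self):
        # a 90-degree symmetric phantom projects symmetrically at +-theta
        vol = sphere_phantom(n=32, radius_vox=7.0)
        tp = project_tilt_series(vol, np.array([25.0]))
        tm = project_tilt_series(vol, np.array([-25.0]))
        assert np.allclose(tp.sinogram[0], tm.sinogram[0][:, ::-1],
                           atol=1e-9)

    def test_default_angle_range(self):
        ang = default_angles()
        assert ang[0] == -65.0 and ang[-1] == 65.0 and len(ang) == 131

    def test_rotation_unsafe_volume_rejected(self):
        vol = LACVolume(np.ones((16, 16, 16)) * 0.1, 13.0)
        with pytest.raises(ValueError):
            project_tilt_series(vol, np.array([0.0]))

    def test_forward_adjoint_consistency(self, rng):
        # <A x, y> == <x, A^T y> exactly (sparse-matrix transpose)
        a = projector_matrix(20, 20, 33.0)
        x = rng.normal(size=400)
        y = rng.normal(size=a.shape[0])
        assert np.dot(a @ x, y) == pytest.approx(
            np.dot(x, a.T @ y), rel=1e-10)


class TestSIRT:
    def test_full_angle_reconstruction_accuracy(self):
        # band-limited phantom: avoids the voxel-edge model mismatch that
        # dominates hard-sphere reconstructions
        z, y, x = np.meshgrid(np.arange(32) - 15.5, np.arange(4) - 1.5,
                              np.arange(32) - 15.5, indexing="ij")
        data = 0.2 * np.exp(-(z**2 + y**2 + x**2) / (2 * 5.0**2))
        data[(z**2 + x**2) > 14**2] = 0.0
        vol = LACVolume(data, 13.0)
        ts = project_tilt_series(vol, np.arange(-90.0, 90.0, 2.0))
        rec, resid = sirt_reconstruct(ts, n_iterations=50)
        rng_val = data.max() - data.min()
        rmse = np.sqrt(np.mean((rec.data - data) ** 2))
        assert rmse < 0.05 * rng_val
        assert np.all(np.diff(resid) <= 1e-12)

    def test_hard_sphere_reconstruction_sane(self):
        vol = sphere_phantom(n=32, radius_vox=8.0, lac=0.2, ny=4)
        ts = project_tilt_series(vol, np.arange(-90.0, 90.0, 2.0))
        rec, _ = sirt_reconstruct(ts, n_iterations=50)
        rmse = np.sqrt(np.mean((rec.data - vol.data) ** 2))
        assert rmse < 0.10 * (vol.data.max() - vol.data.min())

    def test_missing_wedge_elongates_z(self):
        # limited tilt range stretches features along the beam axis,
        # motivating the fiducial-based f_mw correction
        vol = sphere_phantom(n=32, radius_vox=6.0, lac=0.2, ny=4)
        ts = project_tilt_series(vol, default_angles())
        rec, _ = sirt_reconstruct(ts, n_iterations=20)
        sl = rec.data[:, 2, :]
        half = sl.max() / 2
        z_extent = np.count_nonzero(sl.max(axis=1) > half)
        x_extent = np.count_nonzero(sl.max(axis=0) > half)
        assert z_extent / x_extent > 1.0

    def test_no_projections_errors(self):
        ts = TiltSeries(np.zeros((0, 4, 4)), np.zeros(0), 13.0)
        with pytest.raises(ValueError):
            sirt_reconstruct(ts)


class TestFSC:
    def test_self_correlation_is_unity(self, rng):
        v = rng.normal(size=(24, 24, 24))
        _, fsc, _ = fsc_curve(v, v, 13.0)
        assert np.allclose(fsc, 1.0)

    def test_correction_maps_third_to_half(self):
        assert corrected_fsc(np.array([1 / 3]))[0] == pytest.approx(0.5)

    def test_correction_monotone(self):
        x = np.linspace(-0.99, 1.0, 100)
        y = corrected_fsc(x)
        assert np.all(np.diff(y) > 0)

    def test_independent_noise_decorrelates(self, rng):
        a = rng.normal(size=(32, 32, 32))
        b = rng.normal(size=(32, 32, 32))
        _, fsc, counts = fsc_curve(a, b, 13.0)
        sel = counts > 50
        assert np.all(np.abs(fsc[sel]) < 3.0 / np.sqrt(counts[sel] / 2))

    def test_symmetry(self, rng):
        a = rng.normal(size=(16, 16, 16))
        b = a + rng.normal(size=(16, 16, 16))
        _, f1, _ = fsc_curve(a, b, 13.0)
        _, f2, _ = fsc_curve(b, a, 13.0)
        assert np.allclose(f1, f2)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            fsc_curve(np.zeros((8, 8, 8)), np.zeros((8, 8, 9)), 13.0)

    def test_resolution_crossing_on_filtered_pair(self, rng):
        # two half-volumes sharing low-frequency signal with independent
        # high-frequency noise cross the criterion at a finite frequency
        from scipy.ndimage import gaussian_filter

        signal = gaussian_filter(rng.normal(size=(32, 32, 32)), 2.0)
        a = signal + 0.05 * rng.normal(size=signal.shape)
        b = signal + 0.05 * rng.normal(size=signal.shape)
        curve = fsc_resolution(a, b, voxel_nm=13.0, criterion=0.5)
        assert curve.resolution_nm is not None
        # coarser than the half-pitch Nyquist limit (one voxel edge)
        assert 13.0 < curve.resolution_nm < 200.0

    def test_even_odd_split(self):
        vol = sphere_phantom(n=16, radius_vox=4.0, ny=2)
        ts = project_tilt_series(vol, np.arange(-10.0, 10.5, 1.0))
        e, o = ts.split_even_odd()
        assert len(e.angles_deg) + len(o.angles_deg) == len(ts.angles_deg)
        assert np.all(np.diff(e.angles_deg) > 0)
        assert e.angles_deg[0] == ts.angles_deg[0]
        assert o.angles_deg[0] == ts.angles_deg[1]
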