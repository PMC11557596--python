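"""Toy parallel-beam tilt-series forward model.

X-ray transmission through a specimen of linear absorption coefficient
LAC follows Beer-Lambert attenuation: I = I0 exp(-integral LAC dt), so the
line integral of LAC along each ray equals -ln(I/I0).  The forward model
rotates the beam about the y axis (tilt axis), default angles -65..+65
degrees in 1-degree steps — a limited range leaving a missing wedge in
Fourier space that elongates reconstructed features along z.

Projection is implemented as a sparse matrix per tilt angle acting on each
(z, x) slice, with bilinear interpolation weights in [0, 1]; the matrix
transpose is the exact adjoint, which SIRT relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from mesochrom.tomo.volume import LACVolume

__all__ = ["TiltSeries", "default_angles", "projector_matrix",
           "project_tilt_series"]


def default_angles() -> np.ndarray:
    """Limited tilt range -65..+65 degrees, 1-degree steps."""
    return np.arange(-65.0, 65.0 + 0.5, 1.0)


@dataclass
class TiltSeries:
    """Projection images (one per angle) with geometry metadata.

    ``sinogram`` holds -ln(I/I0) images of shape (n_angles, ny, nx);
    ``intensity`` the corresponding transmitted intensities I/I0 * I0.
    """

    sinogram: np.ndarray
    angles_deg: np.ndarray
    pixel_nm: float
    i0: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sinogram.shape[0] != len(self.angles_deg):
            raise ValueError("one image per angle required")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.pixel_nm <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def intensity(self) -> np.ndarray:
        return self.i0 * np.exp(-self.sinogram)

    def split_even_odd(self) -> tuple["TiltSeries", "TiltSeries"]:
        """Alternate projections by index into two half series."""
        e = TiltSeries(self.sinogram[0::2], self.angles_deg[0::2],
                       self.pixel_nm, self.i0)
        o = TiltSeries(self.sinogram[1::2], self.angles_deg[1::2],
                       self.pixel_nm, self.i0)
        return e, o


def projector_matrix(nz: int, nx: int, angle_deg: float,
                     step: float = 0.5) -> sparse.csr_matrix:
    """Sparse line-integral operator for one (z, x) slice at one angle.

    Rows are detector bins (nx of them along the rotated x axis), columns
    flattened (z, x) voxels.  Rays are sampled at ``step``-voxel intervals
    with bilinear weights; weights are scaled by the step so that the
    matrix approximates the continuous line integral in voxel units.
    """
    th = np.deg2rad(angle_deg)
    cz, cx = (nz - 1) / 2.0, (nx - 1) / 2.0
    n_det = nx
    us = np.arange(n_det) - cx
    t_half = 0.5 * np.hypot(nz, nx)
    ts = np.arange(-t_half, t_half + step, step)

    # ray points: z = -u sin + t cos, x = u cos + t sin (about slice centre)
    z = -us[:, None] * np.sin(th) + ts[None, :] * np.cos(th) + cz
    x = us[:, None] * np.cos(th) + ts[None, :] * np.sin(th) + cx

    z0 = np.floor(z).astype(int)
    x0 = np.floor(x).astype(int)
    fz = z - z0
    fx = x - x0
    rows = np.broadcast_to(np.arange(n_det)[:, None], z.shape)

    data, rr, cc = [], [], []
    for dz, dx, w in (
        (0, 0, (1 - fz) * (1 - fx)),
        (0, 1, (1 - fz) * fx),
        (1, 0, fz * (1 - fx)),
        (1, 1, fz * fx),
    ):
        zi = z0 + dz
        xi = x0 + dx
        ok = (zi >= 0) & (zi < nz) & (xi >= 0) & (xi < nx) & (w > 0)
        data.append(w[ok] * step)
        rr.append(rows[ok])
        cc.append(zi[ok] * nx + xi[ok])
    a = sparse.coo_matrix(
        (np.concatenate(data), (np.concatenate(rr), np.concatenate(cc))),
        shape=(n_det, nz * nx),
    )
    return a.tocsr()


def _check_rotation_safe(vol: LACVolume) -> None:
    nz, _, nx = vol.shape
    cz, cx = (nz - 1) / 2.0, (nx - 1) / 2.0
    zz, xx = np.meshgrid(np.arange(nz) - cz, np.arange(nx) - cx,
                         indexing="ij")
    r_safe = min(nz, nx) / 2.0
    outside = (zz**2 + xx**2) > r_safe**2
    support = np.any(vol.data != 0, axis=1)  # (z, x) support
    if np.any(support & outside):
        raise ValueError("volume support extends beyond the rotation-safe "
                         "field (inscribed cylinder)")


def project_tilt_series(volume: LACVolume,
                        angles_deg: np.ndarray | None = None,
                        i0: float = 1.0) -> TiltSeries:
    """Forward-project a LAC volume into a tilt series.

    Returns the sinogram -ln(I/I0) (and, through the TiltSeries, the
    transmitted intensity I = I0 exp(-integral LAC dt)).  LAC in 1/um and
    a voxel edge in nm give dimensionless optical depths.
    """
    if angles_deg is None:
        angles_deg = default_angles()
    angles_deg = np.asarray(angles_deg, dtype=float)
    if np.any(np.abs(angles_deg) > 90):
        raise ValueError("angles must lie within +-90 degrees")
    _check_rotation_safe(volume)
    nz, ny, nx = volume.shape
    # optical depth per voxel step: LAC [1/um] * voxel [nm] * 1e-3
    scale = volume.voxel_nm * 1e-3
    slices = volume.data.transpose(1, 0, 2).reshape(ny, nz * nx)  # y, (z,x)
    sino = np.empty((len(angles_deg), ny, nx))
    for k, ang in enumerate(angles_deg):
        a = projector_matrix(nz, nx, ang)
        sino[k] = (a @ slices.T).T * scale
    return TiltSeries(sino, angles_deg, volume.voxel_nm, i0)
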