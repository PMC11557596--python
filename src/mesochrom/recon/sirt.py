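"""Simultaneous iterative reconstruction (SIRT) of LAC volumes.

Solves the algebraic system  sum_j w_ij LAC(j) = -ln(I_i/I0)  with the
classic row/column-normalised simultaneous update

    x <- x + C A^T R (b - A x),

where R and C are the inverse row and column sums of the projection
matrix A.  On noiseless data the projection residual is non-increasing;
the solver aborts with diagnostics if the residual grows for three
consecutive iterations.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from mesochrom.recon.project import TiltSeries, projector_matrix
from mesochrom.tomo.volume import LACVolume

__all__ = ["sirt_reconstruct", "SIRTDivergence"]


class SIRTDivergence(RuntimeError):
    def __init__(self, iteration: int, residuals: list[float]):
        self.iteration = iteration
        self.residuals = residuals
        super().__init__(
            f"SIRT residual grew for 3 consecutive iterations at iteration "
            f"{iteration}; residual trace tail {residuals[-4:]}"
        )


def sirt_reconstruct(tilt_series: TiltSeries, n_iterations: int = 20,
                     shape_zx: tuple[int, int] | None = None,
                     nonneg: bool = True) -> tuple[LACVolume, np.ndarray]:
    """SIRT reconstruction of a tilt series; returns (volume, residuals).

    ``shape_zx`` defaults to a square (nx, nx) slice.  The returned
    residuals are the per-iteration RMS of ``b - A x`` over all angles and
    slices.
    """
    if tilt_series.sinogram.shape[0] == 0:
        raise ValueError("tilt series has no projections")
    if n_iterations < 1:
        raise ValueError("need at least one iteration")
    n_ang, ny, nx = tilt_series.sinogram.shape
    nz = shape_zx[0] if shape_zx else nx
    nxv = shape_zx[1] if shape_zx else nx

    a = sparse.vstack([
        projector_matrix(nz, nxv, ang) for ang in tilt_series.angles_deg
    ]).tocsr()
    scale = tilt_series.pixel_nm * 1e-3
    a = a * scale  # operator maps LAC [1/um] to optical depth

    row_sum = np.asarray(a.sum(axis=1)).ravel()
    col_sum = np.asarray(a.sum(axis=0)).ravel()
    r_inv = np.where(row_sum > 0, 1.0 / row_sum, 0.0)
    c_inv = np.where(col_sum > 0, 1.0 / col_sum, 0.0)

    b = tilt_series.sinogram.transpose(1, 0, 2).reshape(ny, n_ang * nx)
    x = np.zeros((ny, nz * nxv))
    residuals = []
    grow = 0
    for it in range(n_iterations):
        resid = b - (a @ x.T).T
        residuals.append(float(np.sqrt(np.mean(resid**2))))
        if it >= 1 and residuals[-1] > residuals[-2] * (1 + 1e-12):
            grow += 1
            if grow >= 3:
                raise SIRTDivergence(it, residuals)
        else:
            grow = 0
        x = x + (a.T @ (resid * r_inv[None, :]).T).T * c_inv[None, :]
        if nonneg:
            np.clip(x, 0.0, None, out=x)
    vol = x.reshape(ny, nz, nxv).transpose(1, 0, 2)
    return LACVolume(vol, tilt_series.pixel_nm), np.array(residuals)
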