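"""Synthetic 2D mask pairs for registration round-trips.

The fixed mask is a smooth star-convex nucleus-like blob (low-order
harmonic perturbation of a disc); the moving mask is the fixed mask
carried through the *inverse* of a known similarity transform with
anti-aliased re-binarisation, so that registering moving onto fixed
should recover the transform.
"""

from __future__ import annotations

import numpy as np
from skimage import transform as sktf

from mesochrom.register.affine import AffineTransform2D

__all__ = ["generate_mask_pair", "blob_mask"]


def blob_mask(shape: tuple[int, int] = (256, 256), radius_frac: float = 0.28,
              n_harmonics: int = 4, amplitude: float = 0.12,
              seed: int = 0) -> np.ndarray:
    """Smooth star-convex binary blob centred in the frame."""
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    th = np.arctan2(yy - cy, xx - cx)
    r0 = radius_frac * min(h, w)
    bound = np.full_like(th, r0)
    for k in range(2, 2 + n_harmonics):
        a = amplitude * rng.uniform(0.3, 1.0) * r0 / k
        phi = rng.uniform(0, 2 * np.pi)
        bound = bound + a * np.cos(k * th + phi)
    return r <= bound


def generate_mask_pair(
    shape: tuple[int, int] = (256, 256),
    transform: AffineTransform2D | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, AffineTransform2D]:
    """(fixed, moving, true_transform) with moving = T^{-1}(fixed).

    ``transform`` maps moving -> fixed coordinates.  Raises when the
    transformed mask leaves the frame.
    """
    if transform is None:
        transform = AffineTransform2D(1.0, 0.0, (0.0, 0.0))
    fixed = blob_mask(shape, seed=seed)
    # skimage warp pulls output pixels through the *inverse* map: to get
    # moving = T^{-1} applied to fixed content, warp with T itself.
    m = transform.matrix
    warped = sktf.warp(fixed.astype(float), inverse_map=sktf.AffineTransform(m),
                       order=1, output_shape=shape)
    moving = warped >= 0.5
    if not moving.any():
        raise ValueError("transform maps the mask outside the frame")
    # frame-edge check: mask content must not be clipped
    edge = np.zeros(shape, dtype=bool)
    edge[0, :] = edge[-1, :] = True
    edge[:, 0] = edge[:, -1] = True
    if (moving & edge).any():
        raise ValueError("transform maps the mask outside the frame")
    return fixed, moving, transform
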