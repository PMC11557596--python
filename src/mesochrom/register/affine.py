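"""Boundary-based isotropic affine registration of 2D masks.

Light-microscopy and X-ray projections of the same cell are aligned by an
isotropic similarity transform (uniform scale, rotation, translation)
fitted to the ordered boundary contours of the segmented masks.  The
optimiser is initialised from centroids and second-moment principal axes
and refined gradient-free (Nelder-Mead) on the symmetric mean
nearest-neighbour distance between boundary point sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from skimage import measure

__all__ = ["AffineTransform2D", "RegistrationResult", "register_masks"]


@dataclass(frozen=True)
class AffineTransform2D:
    """Isotropic similarity transform p' = s R(theta) p + t (x, y order)."""

    scale: float
    rotation_deg: float
    translation: tuple[float, float]

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        m = np.eye(3)
        m[:2, :2] = self.scale * r
        m[:2, 2] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform (n, 2) points in (x, y) order."""
        p = np.asarray(points, dtype=float)
        m = self.matrix
        return p @ m[:2, :2].T + m[:2, 2]

    def inverse(self) -> "AffineTransform2D":
        th = np.deg2rad(self.rotation_deg)
        r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        t = -(r.T @ np.asarray(self.translation)) / self.scale
        return AffineTransform2D(1.0 / self.scale, -self.rotation_deg,
                                 (float(t[0]), float(t[1])))

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """self o other (apply ``other`` first)."""
        m = self.matrix @ other.matrix
        scale = float(np.sqrt(np.linalg.det(m[:2, :2])))
        rot = float(np.rad2deg(np.arctan2(m[1, 0], m[0, 0])))
        return AffineTransform2D(scale, rot, (float(m[0, 2]), float(m[1, 2])))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "scale": self.scale, "rotation_deg": self.rotation_deg,
            "translation": list(self.translation)}))

    @classmethod
    def from_json(cls, path: str | Path) -> "AffineTransform2D":
        d = json.loads(Path(path).read_text())
        return cls(d["scale"], d["rotation_deg"], tuple(d["translation"]))


@dataclass
class RegistrationResult:
    transform: AffineTransform2D
    residual: float              # mean symmetric boundary distance (pixels)
    residual_physical: float     # same, in nm (residual * pixel size)
    low_confidence: bool = False


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    """Ordered boundary contour of the dominant component, (x, y) order."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no boundary")
    c = max(contours, key=len)  # dominant component
    return c[:, ::-1]  # (row, col) -> (x, y)


def _symmetric_distance(fixed_tree: cKDTree, fixed_pts: np.ndarray,
                        moving_pts: np.ndarray) -> float:
    d1, _ = fixed_tree.query(moving_pts)
    d2, _ = cKDTree(moving_pts).query(fixed_pts)
    return 0.5 * (d1.mean() + d2.mean())


def _moments_init(fixed: np.ndarray, moving: np.ndarray
                  ) -> list[AffineTransform2D]:
    """Centroid + second-moment candidates (axis is direction-ambiguous)."""
    def props(pts):
        c = pts.mean(axis=0)
        q = pts - c
        cov = q.T @ q / len(q)
        evals, evecs = np.linalg.eigh(cov)
        ang = np.arctan2(evecs[1, -1], evecs[0, -1])
        spread = np.sqrt(evals.sum())
        return c, ang, spread

    cf, af, sf = props(fixed)
    cm, am, sm = props(moving)
    scale = sf / sm if sm > 0 else 1.0
    cands = []
    for extra in (0.0, np.pi):
        rot = np.rad2deg(af - am + extra)
        th = np.deg2rad(rot)
        r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        t = cf - scale * (r @ cm)
        cands.append(AffineTransform2D(scale, float(rot),
                                       (float(t[0]), float(t[1]))))
    return cands


def register_masks(fixed_mask: np.ndarray, moving_mask: np.ndarray,
                   pixel_nm: float = 1.0,
                   low_confidence_residual: float = 5.0
                   ) -> RegistrationResult:
    """Similarity transform carrying the moving mask onto the fixed mask.

    Both masks must be non-empty with a single dominant connected
    component.  The residual is the symmetric mean boundary distance after
    alignment; results with residual above ``low_confidence_residual``
    pixels are flagged low-confidence rather than rejected.
    """
    fixed_pts = _boundary_points(fixed_mask)
    moving_pts = _boundary_points(moving_mask)
    fixed_tree = cKDTree(fixed_pts)

    def cost(x):
        t = AffineTransform2D(np.exp(x[0]), x[1], (x[2], x[3]))
        return _symmetric_distance(fixed_tree, fixed_pts,
                                   t.apply(moving_pts))

    best = None
    for cand in _moments_init(fixed_pts, moving_pts):
        x0 = np.array([np.log(cand.scale), cand.rotation_deg,
                       cand.translation[0], cand.translation[1]])
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-6,
                                "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    t = AffineTransform2D(float(np.exp(best.x[0])), float(best.x[1]),
                          (float(best.x[2]), float(best.x[3])))
    resid = float(best.fun)
    return RegistrationResult(
        transform=t,
        residual=resid,
        residual_physical=resid * pixel_nm,
        low_confidence=resid > low_confidence_residual,
    )
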