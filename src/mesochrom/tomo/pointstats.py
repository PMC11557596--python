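"""Spatial statistics of segmented domain centroids.

k-nearest-neighbour separations, the confinement-corrected pair
correlation function with the first-peak coordination number

    z = 4 pi rho_MD  integral_{r1}^{r2} r^2 g(r) dr,

(r1 = reference-particle radius, r2 = edge of the first g(r) peak), and
maximum-likelihood skew-normal fits to domain-size distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from mesochrom.polymer.observables import ObservableCurve, confined_rdf

__all__ = ["knn_distances", "RDFResult", "domain_rdf_and_zc",
           "SkewNormalFit", "fit_skew_normal"]


def knn_distances(centroids: np.ndarray, k_max: int = 10
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-point distances to the k nearest neighbours, k = 1..k_max.

    Returns ``(dist, pooled)`` where ``dist`` has shape (n_points, k)
    with columns non-decreasing in k, and ``pooled`` is the flattened
    cumulative pool of all k-NN distances.  ``k_max`` is truncated (with a
    warning) when there are fewer than k_max + 1 points.
    """
    pts = np.asarray(centroids, dtype=float)
    n = pts.shape[0]
    if n < 2:
        raise ValueError("need at least 2 centroids")
    if n < k_max + 1:
        warnings.warn(f"only {n} centroids; truncating k_max to {n - 1}",
                      RuntimeWarning, stacklevel=2)
        k_max = n - 1
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=k_max + 1)
    dist = d[:, 1:]  # drop self
    return dist, dist.ravel()


@dataclass
class RDFResult:
    """g(r) of domain centroids plus the first-peak coordination number."""

    bins_nm: np.ndarray
    g: np.ndarray
    rho: float               # bulk number density (1/nm^3)
    r1_nm: float             # reference-particle radius
    r2_nm: float | None      # edge of the first peak; None if undetectable
    z: float | None          # coordination number; None if r2 undetectable
    curve: ObservableCurve | None = field(default=None, repr=False)


def _first_peak_edge(x: np.ndarray, y: np.ndarray, smooth_bins: int = 3
                     ) -> float | None:
    """First local minimum of the smoothed curve beyond its first maximum."""
    y = np.array(y, dtype=float)
    filled = np.where(np.isfinite(y), y, 0.0)
    if smooth_bins > 1:
        kern = np.ones(smooth_bins) / smooth_bins
        filled = np.convolve(filled, kern, mode="same")
    if len(filled) < 5:
        return None
    imax = int(np.argmax(filled))
    if filled[imax] <= 0:
        return None
    for i in range(imax + 1, len(filled) - 1):
        if filled[i] <= filled[i - 1] and filled[i] < filled[i + 1]:
            return float(x[i])
    return None


def domain_rdf_and_zc(
    centroids_nm: np.ndarray,
    region_radius_nm: float | None = None,
    region_volume_nm3: float | None = None,
    mean_domain_radius_nm: float = 40.0,
    bin_width_nm: float = 13.0,
    smooth_bins: int = 3,
) -> RDFResult:
    """Pair correlation of domain centroids and the coordination number
    from the area under the first peak.

    The confinement correction needs a bounding geometry: pass the region
    radius directly, or a region volume (converted to the equivalent
    sphere).  Centroids are re-centred on their mean.  ``z`` is computed by
    trapezoidal quadrature of ``4 pi rho r^2 g(r)`` from ``r1`` (the mean
    domain radius) to ``r2`` (first-peak edge); masked (empty) bins count
    as zero.  When no first-peak edge is detectable, ``z`` is None.
    """
    pts = np.asarray(centroids_nm, dtype=float)
    if pts.shape[0] < 10:
        raise ValueError("need at least 10 centroids for a stable estimate")
    pts = pts - pts.mean(axis=0)
    if region_radius_nm is None:
        if region_volume_nm3 is None:
            # smallest enclosing sphere approximated by max centroid radius
            region_radius_nm = float(np.linalg.norm(pts, axis=1).max()) * 1.05
        else:
            region_radius_nm = (3.0 * region_volume_nm3 / (4 * np.pi)) ** (1 / 3)
    rmax = np.linalg.norm(pts, axis=1).max()
    if rmax > region_radius_nm:
        region_radius_nm = float(rmax) * 1.0001  # numerical containment
    edges = np.arange(0.0, 2.0 * region_radius_nm + bin_width_nm, bin_width_nm)
    curve = confined_rdf(pts, None, region_radius_nm, edges)
    rho = pts.shape[0] / (4.0 / 3.0 * np.pi * region_radius_nm**3)

    r2 = _first_peak_edge(curve.x, curve.y, smooth_bins)
    z = None
    if r2 is not None and r2 > mean_domain_radius_nm:
        xs = curve.x
        gs = np.where(np.isfinite(curve.y), curve.y, 0.0)
        sel = (xs >= mean_domain_radius_nm) & (xs <= r2)
        if sel.sum() >= 1:
            # rectangle (bin-sum) quadrature: robust to single-bin peaks
            z = float(4.0 * np.pi * rho *
                      np.sum(xs[sel] ** 2 * gs[sel]) * bin_width_nm)
    if z is None:
        warnings.warn("no detectable first peak; coordination number "
                      "undefined", RuntimeWarning, stacklevel=2)
    return RDFResult(curve.x, curve.y, rho, mean_domain_radius_nm, r2, z,
                     curve)


@dataclass
class SkewNormalFit:
    location: float
    scale: float
    alpha: float
    alpha_ci: tuple[float, float]
    n: int


def fit_skew_normal(diameters: np.ndarray, n_boot: int = 200,
                    seed: int = 0) -> SkewNormalFit:
    """Maximum-likelihood skew-normal fit with a bootstrap CI on the
    skewness parameter alpha.  Requires >= 20 non-degenerate samples."""
    x = np.asarray(diameters, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 samples")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (zero-variance) input")
    a, loc, scale = stats.skewnorm.fit(x)
    if n_boot == 0:
        return SkewNormalFit(float(loc), float(scale), float(a),
                             (np.nan, np.nan), int(x.size))
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        xb = rng.choice(x, size=x.size, replace=True)
        try:
            boot[i] = stats.skewnorm.fit(xb)[0]
        except Exception:  # rare optimisation failure on a resample
            boot[i] = np.nan
    lo, hi = np.nanpercentile(boot, [2.5, 97.5])
    return SkewNormalFit(float(loc), float(scale), float(a),
                         (float(lo), float(hi)), int(x.size))
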