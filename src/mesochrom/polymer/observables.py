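"""Dynamical and structural observables on polymer trajectories.

MSD and the overlap function are computed per bead type over steady-state
snapshots, averaging over all available time origins (a statistics
improvement over a single origin; flagged in the curve metadata).  The
radial distribution function uses a confinement-corrected ideal-gas
normalisation: the expected count in a shell is rho times the exact volume
of the intersection between the shell around each reference bead and the
spherical cavity, so g(r) -> 1 at large r for unstructured points without
periodic images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ObservableCurve", "msd", "overlap_function", "confined_rdf",
           "shell_cavity_volume", "fit_stretched_exponential"]


@dataclass
class ObservableCurve:
    """A 1D observable: abscissa, ordinate, per-point sample counts."""

    x: np.ndarray
    y: np.ndarray
    counts: np.ndarray
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("abscissa must be strictly increasing")


def _steady_block(trajectory, bead_type):
    pos = trajectory.steady_positions()
    if pos.shape[0] < 2:
        raise ValueError("need at least 2 steady-state snapshots")
    if bead_type is None:
        sel = np.ones(trajectory.bead_type.shape[0], dtype=bool)
    else:
        sel = trajectory.bead_type == bead_type
        if not sel.any():
            raise ValueError(f"no beads of type {bead_type}")
    return pos[:, sel], trajectory.bead_diameter[sel]


def _lag_indices(trajectory, lag_times, n_snaps):
    dt_snap = trajectory.config.snap_stride * trajectory.config.dt
    if lag_times is None:
        lags = np.arange(n_snaps)
    else:
        lags = np.rint(np.asarray(lag_times, dtype=float) / dt_snap).astype(int)
        if np.any(lags < 0) or np.any(lags >= n_snaps):
            raise ValueError("lag times outside trajectory span")
    return np.unique(lags), dt_snap


def msd(trajectory, bead_type=None, lag_times=None) -> ObservableCurve:
    """Mean squared displacement ⟨r²(t)⟩ for one bead type.

    Averages over beads of the type and over all steady-state time
    origins.  Lag 0 is exactly zero.
    """
    pos, _ = _steady_block(trajectory, bead_type)
    s = pos.shape[0]
    lags, dt_snap = _lag_indices(trajectory, lag_times, s)
    vals = np.empty(len(lags))
    counts = np.empty(len(lags), dtype=int)
    for k, lag in enumerate(lags):
        if lag == 0:
            vals[k] = 0.0
            counts[k] = pos.shape[1] * s
            continue
        d = pos[lag:] - pos[:-lag] if lag < s else None
        sq = np.sum(d * d, axis=2)
        vals[k] = sq.mean()
        counts[k] = sq.size
    return ObservableCurve(
        lags * dt_snap, vals, counts,
        label=f"msd[{bead_type}]",
        meta={"time_origin_averaged": True},
    )


def overlap_function(trajectory, bead_type=None, lag_times=None) -> ObservableCurve:
    """Overlap function Q(t): fraction of beads displaced less than one
    bead diameter over lag t (step function theta(x)=1 for x>0, 0 for x<=0,
    so a displacement exactly equal to the diameter counts as moved)."""
    pos, sigma = _steady_block(trajectory, bead_type)
    s = pos.shape[0]
    lags, dt_snap = _lag_indices(trajectory, lag_times, s)
    vals = np.empty(len(lags))
    counts = np.empty(len(lags), dtype=int)
    for k, lag in enumerate(lags):
        if lag == 0:
            vals[k] = 1.0
            counts[k] = pos.shape[1] * s
            continue
        d = pos[lag:] - pos[:-lag]
        disp = np.sqrt(np.sum(d * d, axis=2))
        moved_less = disp < sigma[None, :]
        vals[k] = moved_less.mean()
        counts[k] = disp.size
    return ObservableCurve(
        lags * dt_snap, vals, counts,
        label=f"overlap[{bead_type}]",
        meta={"time_origin_averaged": True},
    )


def shell_cavity_volume(r_edges: np.ndarray, d: np.ndarray,
                        cavity_radius: float) -> np.ndarray:
    """Exact volume of shell [r_k, r_k+1] ∩ cavity, per reference point at
    centre distance d.

    For a point at distance d from the cavity centre (radius R), the area
    of the sphere of radius r around it lying inside the cavity is the
    spherical cap 4 pi r^2 (c+1)/2 with c = (R^2 - d^2 - r^2)/(2 d r) for
    R-d < r < R+d, the full sphere for r <= R-d, zero beyond R+d.  The
    shell volume is the closed-form radial integral of that area.
    Returns an array (len(d), len(r_edges)-1).
    """
    r_edges = np.asarray(r_edges, dtype=float)
    d = np.atleast_1d(np.asarray(d, dtype=float))
    R = cavity_radius
    tiny = 1e-12 * max(R, 1.0)
    dd = np.maximum(d, tiny)[:, None]
    central = (d <= tiny)[:, None]  # centre point: no cap branch needed

    def antiderivative(r):
        # integral of the inside-cavity sphere area:
        #   full branch F0 = 4 pi r^3 / 3        for r <= R - d
        #   cap branch  F1 = 2 pi r^3/3 + (pi/d)((R^2-d^2) r^2/2 - r^4/4)
        r = np.asarray(r, dtype=float)
        lo = np.clip(r, 0.0, np.maximum(R - dd, 0.0))
        f = 4.0 * np.pi / 3.0 * lo**3
        a0 = np.abs(R - dd)
        a = np.clip(r, a0, R + dd)

        def f1(x):
            return (2.0 * np.pi / 3.0 * x**3
                    + np.pi / dd * ((R**2 - dd**2) * x**2 / 2.0 - x**4 / 4.0))

        cap = np.where(central, 0.0, f1(a) - f1(a0))
        return f + cap

    vals = antiderivative(r_edges[None, :])
    return np.diff(vals, axis=1)


def confined_rdf(
    positions: np.ndarray,
    pair_kind: str | None,
    cavity_radius: float,
    bin_edges: np.ndarray,
    bead_type: np.ndarray | None = None,
) -> ObservableCurve:
    """Pair correlation g(r) inside a spherical cavity.

    ``pair_kind`` is "AA", "AB", "BB" (requires ``bead_type``) or None for
    all pairs.  The pairwise-distance histogram is normalised by
    rho * V_shell with V_shell the exact shell-cavity intersection volume
    averaged over reference positions.  Bins with zero expected count are
    masked (NaN), not zero.
    """
    positions = np.asarray(positions, dtype=float)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be increasing")
    rr = np.linalg.norm(positions, axis=1)
    if np.any(rr > cavity_radius + 1e-9):
        raise ValueError("all points must lie inside the cavity")

    if pair_kind is None:
        ref_idx = tgt_idx = np.arange(positions.shape[0])
    else:
        if bead_type is None:
            raise ValueError("bead_type required for typed pair_kind")
        a = np.where(bead_type == 0)[0]
        b = np.where(bead_type == 1)[0]
        ref_idx, tgt_idx = {
            "AA": (a, a), "AB": (a, b), "BA": (b, a), "BB": (b, b)
        }[pair_kind]

    ref = positions[ref_idx]
    tgt = positions[tgt_idx]
    same = pair_kind in (None, "AA", "BB")
    dists = np.linalg.norm(ref[:, None, :] - tgt[None, :, :], axis=2)
    if same:
        np.fill_diagonal(dists, -1.0)  # exclude self-pairs
    counts, _ = np.histogram(dists[dists >= 0], bins=bin_edges)

    vol = 4.0 / 3.0 * np.pi * cavity_radius**3
    n_tgt = len(tgt_idx) - 1 if same else len(tgt_idx)
    rho = n_tgt / vol
    vshell = shell_cavity_volume(bin_edges, np.linalg.norm(ref, axis=1),
                                 cavity_radius)
    expected = rho * vshell.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        # empty shells are undefined (masked), not zero
        g = np.where((expected > 0) & (counts > 0), counts / expected, np.nan)
    centers = 0.5 * (bin_edges[1:] + bin_edges[:-1])
    return ObservableCurve(centers, g, counts, label=f"g(r)[{pair_kind}]",
                           meta={"rho": rho, "cavity_radius": cavity_radius})


def fit_stretched_exponential(curve: ObservableCurve,
                              p0: tuple[float, float, float] | None = None
                              ) -> tuple[float, float, float]:
    """Least-squares fit of A * exp(-(t/tau)^beta) to a decay curve.

    A plain curve-fit utility (e.g. for overlap-function decays); returns
    (A, tau, beta).  No unit conversion is applied: tau is in the curve's
    abscissa units.
    """
    from scipy.optimize import curve_fit

    def f(t, a, tau, beta):
        return a * np.exp(-((t / tau) ** beta))

    sel = np.isfinite(curve.y) & (curve.x > 0)
    if sel.sum() < 4:
        raise ValueError("need at least 4 finite points")
    if p0 is None:
        p0 = (float(np.max(curve.y[sel])), float(np.median(curve.x[sel])),
              1.0)
    popt, _ = curve_fit(f, curve.x[sel], curve.y[sel], p0=p0,
                        bounds=([0, 1e-12, 0.05], [np.inf, np.inf, 4.0]),
                        maxfev=10000)
    return float(popt[0]), float(popt[1]), float(popt[2])
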