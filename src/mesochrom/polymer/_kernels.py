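"""Numba kernels for the confined bead-spring polymer.

All kernels work in reduced units (EC/A bead diameter = 1, k_B T = 1 unless
stated).  The interaction set is

* soft Gaussian "blob" exclusion between all pairs within ``rcut_factor *
  sigma_ab`` (no hard cores),
* FENE springs between chain neighbours,
* a heterochromatin affinity between HC/B pairs with an interior minimum at
  the optimal separation ``d_B``,
* a repulsive, truncated-and-shifted (WCA) wall at the spherical cavity.

The neighbour-list contract is exactness: energies/forces computed through
the Verlet list are identical (to floating-point roundoff) to an all-pairs
evaluation with the same cutoffs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "build_pairs",
    "forces_energy",
    "run_bd",
]


@njit(cache=True)
def build_pairs(pos, cutoff):
    """All pairs (i<j) within ``cutoff``; two-pass count/fill."""
    n = pos.shape[0]
    c2 = cutoff * cutoff
    count = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if dx * dx + dy * dy + dz * dz < c2:
                count += 1
    pi = np.empty(count, dtype=np.int64)
    pj = np.empty(count, dtype=np.int64)
    k = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if dx * dx + dy * dy + dz * dz < c2:
                pi[k] = i
                pj[k] = j
                k += 1
    return pi, pj


@njit(cache=True, fastmath=True)
def forces_energy(
    pos,
    sigma,
    is_b,
    pair_i,
    pair_j,
    eps_vex,
    avex_coeff,
    fene_k,
    fene_r0_factor,
    eps_hc,
    alpha_hc,
    d_b,
    eps_wall,
    rcut_factor,
    cav_r,
    forces,
):
    """Accumulate forces into ``forces`` (zeroed here); return total potential.

    Nonbonded terms run over the supplied pair list (which must contain every
    pair within ``rcut_factor * sigma_ab``); FENE runs over chain neighbours
    i, i+1; the wall term over all beads.  Returns NaN energy if a FENE bond
    is at or beyond its maximum extension.
    """
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    energy = 0.0

    for p in range(pair_i.shape[0]):
        i = pair_i[p]
        j = pair_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        sab = 0.5 * (sigma[i] + sigma[j])
        rc = rcut_factor * sab
        if r2 < rc * rc:
            avex = avex_coeff / (sab * sab)
            uvex = eps_vex * np.exp(-avex * r2)
            energy += uvex
            fr = 2.0 * avex * uvex  # -(1/r) dU/dr
            if eps_hc != 0.0 and is_b[i] and is_b[j]:
                # short-ranged attraction: dimensionless quadratic
                # prefactor (zero at the origin) times a Gaussian well of
                # width 1/sqrt(alpha) near the optimal separation d_B
                r = np.sqrt(r2)
                s = r2 / (d_b * d_b)
                ex = np.exp(-alpha_hc * (r - d_b) ** 2)
                energy += -eps_hc * s * ex
                # -(1/r) dU/dr
                fr += eps_hc * ex * (2.0 / (d_b * d_b)
                                     - 2.0 * alpha_hc * s * (r - d_b) / r)
            forces[i, 0] += fr * dx
            forces[i, 1] += fr * dy
            forces[i, 2] += fr * dz
            forces[j, 0] -= fr * dx
            forces[j, 1] -= fr * dy
            forces[j, 2] -= fr * dz

    # FENE bonds along the chain
    for i in range(n - 1):
        j = i + 1
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        sab = 0.5 * (sigma[i] + sigma[j])
        r0 = fene_r0_factor * sab
        x = r2 / (r0 * r0)
        if x >= 1.0:
            return np.nan
        energy += -12.0 * fene_k * r0 * r0 * np.log(1.0 - x)
        fr = -24.0 * fene_k / (1.0 - x)
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz

    # WCA wall (repulsive, truncated and shifted at 2^(1/6) sigma_i from wall)
    for i in range(n):
        rr = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
        riw = cav_r - rr
        wcut = 1.122462048309373 * sigma[i]
        if riw < wcut and rr > 1e-12:
            if riw <= 0.0:
                return np.nan
            s6 = (sigma[i] / riw) ** 6
            energy += 4.0 * eps_wall * (s6 * s6 - s6) + eps_wall
            # dU/driw = 4 eps (-12 s12 + 6 s6)/riw ; F = dU/driw * rhat
            dudr = 4.0 * eps_wall * (-12.0 * s6 * s6 + 6.0 * s6) / riw
            fr = dudr / rr
            forces[i, 0] += fr * pos[i, 0]
            forces[i, 1] += fr * pos[i, 1]
            forces[i, 2] += fr * pos[i, 2]
    return energy


@njit(cache=True, fastmath=True)
def run_bd(
    pos,
    sigma,
    is_b,
    n_steps,
    dt,
    kt,
    eta,
    eps_vex,
    avex_coeff,
    fene_k,
    fene_r0_factor,
    eps_hc,
    alpha_hc,
    d_b,
    eps_wall,
    rcut_factor,
    cav_r,
    seed,
    snap_stride,
    snapshots,
    snap_energy,
    skin,
):
    """Overdamped Langevin (Euler-Maruyama) integration in place.

    ``snapshots`` has shape (n_snaps, N, 3) with n_snaps = n_steps//stride + 1
    and receives the initial state in slot 0.  Returns the index of the first
    bead with a non-finite coordinate (integration failure), or -1 on
    success.  The Verlet list is rebuilt whenever any bead has moved more
    than ``skin/2`` since the last build, which keeps list-based energies
    identical to all-pairs.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    disp = np.zeros((n, 3))
    smax = 0.0
    for i in range(n):
        if sigma[i] > smax:
            smax = sigma[i]
    list_cut = rcut_factor * smax + skin
    pi, pj = build_pairs(pos, list_cut)

    # per-bead mobility and noise amplitude
    mob = np.empty(n)
    amp = np.empty(n)
    for i in range(n):
        mob[i] = 1.0 / (3.0 * np.pi * eta * sigma[i])
        amp[i] = np.sqrt(2.0 * kt * mob[i] * dt)

    e0 = forces_energy(
        pos, sigma, is_b, pi, pj,
        eps_vex, avex_coeff, fene_k, fene_r0_factor,
        eps_hc, alpha_hc, d_b, eps_wall, rcut_factor, cav_r, forces,
    )
    snapshots[0] = pos
    snap_energy[0] = e0
    snap_idx = 1

    for step in range(1, n_steps + 1):
        for i in range(n):
            fdt = mob[i] * dt
            for d in range(3):
                dxi = forces[i, d] * fdt + amp[i] * np.random.standard_normal()
                pos[i, d] += dxi
                disp[i, d] += dxi
        # rebuild check
        half_skin2 = 0.25 * skin * skin
        rebuild = False
        for i in range(n):
            d2 = disp[i, 0] ** 2 + disp[i, 1] ** 2 + disp[i, 2] ** 2
            if d2 > half_skin2:
                rebuild = True
                break
        if rebuild:
            pi, pj = build_pairs(pos, list_cut)
            for i in range(n):
                disp[i, 0] = 0.0
                disp[i, 1] = 0.0
                disp[i, 2] = 0.0
        e = forces_energy(
            pos, sigma, is_b, pi, pj,
            eps_vex, avex_coeff, fene_k, fene_r0_factor,
            eps_hc, alpha_hc, d_b, eps_wall, rcut_factor, cav_r, forces,
        )
        if np.isnan(e):
            for i in range(n):
                for d in range(3):
                    if not np.isfinite(pos[i, d]):
                        return i
            return 0
        if step % snap_stride == 0:
            snapshots[snap_idx] = pos
            snap_energy[snap_idx] = e
            snap_idx += 1
    return -1
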