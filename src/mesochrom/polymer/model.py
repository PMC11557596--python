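"""Confined two-type chromatin polymer: state, interactions, forces.

The chain is a linear sequence of beads of two types — euchromatin (EC/A,
diameter 18 nm = 1 reduced length unit) and heterochromatin (HC/B, diameter
25 nm) — confined to a spherical cavity.  Four interactions act:

``vex``
    soft Gaussian blob exclusion between every pair within the cutoff,
    ``eps_vex * exp(-alpha_vex * r^2)`` — overlaps are penalised but not
    forbidden (no hard cores).
``fene``
    finitely extensible nonlinear elastic spring between chain neighbours,
    ``-12 k r0^2 ln[1 - (r/r0)^2]``.
``hc``
    heterochromatin affinity between HC/B pairs,
    ``-eps_HC (r/d_B)^2 exp(-alpha_HC (r - d_B)^2)``: zero at the origin
    (quadratic prefactor), an interior minimum of depth ~eps_HC just
    outside the optimal separation ``d_B = sigma_BB``, and a short,
    independently tunable range ``1/sqrt(alpha_HC)`` (default ~sigma_BB/4).
    The short range is what arrests coarsening into mesoscale clusters
    instead of a single condensate.
``wall``
    repulsive WCA (truncated-shifted Lennard-Jones) acting on the distance
    ``r_iw`` between a bead and the cavity wall, zero beyond
    ``2^{1/6} sigma_i``.

Pair-dependent length scales use the arithmetic mixing rule
``sigma_ab = (sigma_a + sigma_b)/2``; the exclusion width, FENE maximum
extension and cutoffs all scale with ``sigma_ab``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from mesochrom.polymer import _kernels
from mesochrom.units import UnitSystem

EC_A = 0
HC_B = 1

SIGMA_BB_DEFAULT = 25.0 / 18.0

__all__ = [
    "EC_A",
    "HC_B",
    "InteractionParams",
    "PolymerState",
    "build_initial_chain",
    "cavity_radius_for_density",
    "pair_energy",
    "compute_forces",
    "total_energy",
    "hc_minimum_separation",
]


@dataclass(frozen=True)
class InteractionParams:
    """Interaction constants in reduced units.

    ``alpha_vex``, ``fene_r0`` and ``alpha_HC``/``d_B`` are expressed as
    dimensionless coefficients of the relevant pair scale: the exclusion
    width is ``alpha_vex / sigma_ab^2``, the FENE maximum extension
    ``fene_r0 * sigma_ab``, the affinity width ``alpha_HC / sigma_BB^2``
    and the optimal HC separation ``d_B * sigma_BB``.  The nonbonded
    cutoff is ``r_cut_factor * sigma_ab`` (3 sigma by default).
    """

    eps_vex: float = 10.0
    alpha_vex: float = 4.0
    fene_k: float = 1.0
    fene_r0: float = 1.5
    eps_HC: float = 3.0
    alpha_HC: float = 16.0
    d_B: float = 1.0
    eps_wall: float = 1.0
    r_cut_factor: float = 3.0
    sigma_BB: float = SIGMA_BB_DEFAULT

    def __post_init__(self) -> None:
        for name in ("eps_vex", "eps_HC", "eps_wall"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.r_cut_factor <= 0:
            raise ValueError("r_cut_factor must be > 0")
        if self.fene_r0 <= 1.0:
            raise ValueError("fene_r0 must exceed the bond rest separation")

    @property
    def alpha_HC_abs(self) -> float:
        """Affinity width in absolute reduced units (1/length^2)."""
        return self.alpha_HC / self.sigma_BB**2

    @property
    def d_B_abs(self) -> float:
        """Optimal HC separation in absolute reduced units."""
        return self.d_B * self.sigma_BB

    def with_eps_HC(self, eps: float) -> "InteractionParams":
        return replace(self, eps_HC=eps)


@dataclass
class PolymerState:
    """Bead positions and identities of a confined chain.

    Positions are (N, 3) in reduced length; ``bead_type`` holds ``EC_A`` /
    ``HC_B`` codes in chain order; ``bead_diameter`` the per-bead reduced
    diameter (1.0 for EC/A, 25/18 for HC/B).
    """

    positions: np.ndarray
    bead_type: np.ndarray
    bead_diameter: np.ndarray
    cavity_radius: float
    unit_system: UnitSystem = field(default_factory=UnitSystem)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def is_b(self) -> np.ndarray:
        return self.bead_type == HC_B

    def copy(self) -> "PolymerState":
        return PolymerState(
            self.positions.copy(),
            self.bead_type.copy(),
            self.bead_diameter.copy(),
            self.cavity_radius,
            self.unit_system,
        )

    def validate(self, tol: float = 0.05) -> None:
        """Raise if any bead (plus its radius) pokes outside the cavity."""
        r = np.linalg.norm(self.positions, axis=1)
        excess = r + self.bead_diameter / 2 - self.cavity_radius
        if np.any(excess > tol):
            i = int(np.argmax(excess))
            raise ValueError(
                f"bead {i} outside cavity by {excess[i]:.3f} reduced units"
            )


def cavity_radius_for_density(n_beads: int, number_density: float = 0.2) -> float:
    """Cavity radius giving reduced number density N/V."""
    vol = n_beads / number_density
    return (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)


class PlacementError(RuntimeError):
    """Initial chain could not be placed inside the cavity."""


def assign_block_types(n_beads: int, fraction_A: float, mean_block_B: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Alternating geometric blocks of A and B beads.

    Heterochromatin is contiguous along the genome: a 25 nm HC/B bead
    coarse-grains only ~3 kbp, so heterochromatin domains of tens of kbp
    correspond to *runs* of consecutive B beads.  Block lengths are
    geometric with mean ``mean_block_B`` for B and
    ``mean_block_B * fraction_A / (1 - fraction_A)`` for A, preserving the
    overall composition in expectation.
    """
    mean_block_A = mean_block_B * fraction_A / max(1e-12, 1.0 - fraction_A)
    types: list[int] = []
    cur = int(rng.integers(0, 2))
    while len(types) < n_beads:
        mean = mean_block_A if cur == EC_A else mean_block_B
        length = int(rng.geometric(1.0 / mean))
        types.extend([cur] * length)
        cur = 1 - cur
    return np.array(types[:n_beads], dtype=np.int8)


def build_initial_chain(
    n_beads: int,
    fraction_A: float = 0.55,
    cavity_radius: float | None = None,
    unit_system: UnitSystem | None = None,
    seed: int = 0,
    sigma_BB: float = SIGMA_BB_DEFAULT,
    number_density: float = 0.2,
    mean_block_B: float | None = None,
    max_retries: int = 200,
) -> PolymerState:
    """Place the chain as a self-avoiding random walk inside the cavity.

    With ``mean_block_B`` unset, bead types are assigned by a seeded
    shuffle with exact counts (``round(fraction_A * n_beads)`` EC/A
    beads); otherwise by alternating geometric blocks (see
    :func:`assign_block_types`), emulating contiguous heterochromatin
    domains.  Consecutive beads are placed at the pair rest separation
    ``sigma_ab``; self-avoidance is enforced only against immediate
    re-tracing (the soft cores permit overlaps between distant beads).
    Deterministic for a given seed.
    """
    if n_beads < 2:
        raise ValueError("need at least 2 beads")
    if not 0.0 <= fraction_A <= 1.0:
        raise ValueError("fraction_A must be in [0, 1]")
    rng = np.random.default_rng(seed)

    if mean_block_B is None or fraction_A in (0.0, 1.0):
        n_a = round(fraction_A * n_beads)
        types = np.full(n_beads, HC_B, dtype=np.int8)
        types[:n_a] = EC_A
        rng.shuffle(types)
    else:
        types = assign_block_types(n_beads, fraction_A, mean_block_B, rng)
    sigma = np.where(types == EC_A, 1.0, sigma_BB)
    if cavity_radius is None:
        # density-derived radius, floored so tiny chains still fit inside
        # the wall-interaction margin
        cavity_radius = max(cavity_radius_for_density(n_beads, number_density),
                            3.0 * float(sigma.max()))

    pos = np.empty((n_beads, 3))
    # keep starting positions outside the steep wall zone (WCA cutoff)
    wall_margin = 2.0 ** (1.0 / 6.0) * sigma
    max_r0 = cavity_radius - wall_margin[0]
    if max_r0 <= 0:
        raise PlacementError("cavity too small for a single bead")
    pos[0] = rng.uniform(-1, 1, 3) * max_r0 / np.sqrt(3.0)
    for i in range(1, n_beads):
        bond = 0.5 * (sigma[i - 1] + sigma[i])
        placed = False
        for _ in range(max_retries):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            cand = pos[i - 1] + bond * v
            if np.linalg.norm(cand) + wall_margin[i] > cavity_radius:
                continue
            if i >= 2 and np.linalg.norm(cand - pos[i - 2]) < 0.5 * bond:
                continue  # immediate re-tracing
            pos[i] = cand
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place bead {i} after {max_retries} tries; "
                "cavity too small"
            )
    return PolymerState(
        pos, types, sigma, float(cavity_radius), unit_system or UnitSystem()
    )


# ---------------------------------------------------------------------------
# energies and forces


def hc_minimum_separation(params: InteractionParams) -> float:
    """Separation minimising the HC pair energy (zero mutual force),
    located numerically; sits just outside d_B for narrow wells."""
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda r: pair_energy(r, "hc", params),
        bounds=(1e-3, params.r_cut_factor * params.sigma_BB),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def pair_energy(
    r: np.ndarray | float,
    pair_kind: str,
    params: InteractionParams,
    sigma_a: float = 1.0,
    sigma_b: float = 1.0,
) -> np.ndarray | float:
    """Energy of a single interaction term at separation ``r``.

    ``pair_kind`` is one of ``vex``, ``fene``, ``hc``, ``wall``.  For
    ``wall``, ``r`` is the bead-wall distance and ``sigma_a`` the bead
    diameter.  FENE at or beyond the maximum extension returns ``inf``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation must be non-negative")
    sab = 0.5 * (sigma_a + sigma_b)
    rcut = params.r_cut_factor * sab
    if pair_kind == "vex":
        u = params.eps_vex * np.exp(-(params.alpha_vex / sab**2) * r**2)
        return np.where(r <= rcut, u, 0.0)[()]
    if pair_kind == "fene":
        r0 = params.fene_r0 * sab
        with np.errstate(divide="ignore", invalid="ignore"):
            u = -12.0 * params.fene_k * r0**2 * np.log1p(-((r / r0) ** 2))
        return np.where(r >= r0, np.inf, u)[()]
    if pair_kind == "hc":
        a = params.alpha_HC_abs
        d = params.d_B_abs
        rcut_bb = params.r_cut_factor * params.sigma_BB
        # dimensionless (r/d_B)^2 prefactor (zero at origin) times a
        # Gaussian well of width 1/sqrt(alpha) at the optimal separation
        u = -params.eps_HC * (r / d) ** 2 * np.exp(-a * (r - d) ** 2)
        return np.where(r <= rcut_bb, u, 0.0)[()]
    if pair_kind == "wall":
        wcut = 2.0 ** (1.0 / 6.0) * sigma_a
        with np.errstate(divide="ignore", over="ignore"):
            s6 = (sigma_a / r) ** 6
            u = 4.0 * params.eps_wall * (s6**2 - s6) + params.eps_wall
        return np.where(r <= wcut, u, 0.0)[()]
    raise ValueError(f"unknown pair_kind {pair_kind!r}")


def _kernel_args(state: PolymerState, params: InteractionParams):
    return (
        state.positions,
        state.bead_diameter,
        state.is_b,
        params.eps_vex,
        params.alpha_vex,
        params.fene_k,
        params.fene_r0,
        params.eps_HC,
        params.alpha_HC_abs,
        params.d_B_abs,
        params.eps_wall,
        params.r_cut_factor,
        state.cavity_radius,
    )


def compute_forces(
    state: PolymerState, params: InteractionParams
) -> tuple[np.ndarray, float]:
    """Forces ``-dH/dx_i`` on every bead and the total potential energy.

    Raises :class:`FloatingPointError` naming the first offending bead when
    a FENE bond is overextended (non-finite energy).
    """
    pos = state.positions
    sigma = state.bead_diameter
    cutoff = params.r_cut_factor * float(sigma.max())
    pi, pj = _kernels.build_pairs(pos, cutoff)
    forces = np.zeros_like(pos)
    (p, s, b, ev, av, fk, fr0, eh, ah, db, ew, rcf, cr) = _kernel_args(state, params)
    energy = _kernels.forces_energy(
        p, s, b, pi, pj, ev, av, fk, fr0, eh, ah, db, ew, rcf, cr, forces
    )
    if not np.isfinite(energy):
        bad = np.where(~np.all(np.isfinite(forces), axis=1))[0]
        # overextension may produce finite but wrong values only at exactly
        # r = r0; locate the first overextended bond explicitly
        bond = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        r0 = params.fene_r0 * 0.5 * (sigma[:-1] + sigma[1:])
        over = np.where(bond >= r0)[0]
        idx = int(over[0]) if over.size else (int(bad[0]) if bad.size else -1)
        raise FloatingPointError(f"non-finite energy (first offending bead {idx})")
    return forces, float(energy)


def total_energy(state: PolymerState, params: InteractionParams) -> float:
    """Total potential energy of the state (sum of all four terms)."""
    _, e = compute_forces(state, params)
    return e
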