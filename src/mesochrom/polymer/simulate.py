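"""Brownian-dynamics integration of the confined chromatin chain.

The overdamped Langevin equation

    dx_i/dt = -(1/gamma_i) dH/dx_i + sqrt(2 k_B T / gamma_i) xi(t),
    gamma_i = 6 pi eta (sigma_i / 2),

is integrated with the Euler-Maruyama scheme (Gaussian increments of
variance ``2 k_B T dt / gamma_i`` per coordinate) at a default timestep of
1e-4 tau.  A simulation is "in steady state" once the potential energy per
bead has plateaued; the detector fits a straight line to the energy trace
over trailing windows and declares a plateau when the fitted slope falls
below a tolerance (default 1e-4 energy units per tau per bead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from mesochrom.polymer import _kernels
from mesochrom.polymer.model import (
    InteractionParams,
    PolymerState,
    build_initial_chain,
)
from mesochrom.units import UnitSystem

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "step_euler_maruyama",
    "run_simulation",
    "detect_plateau",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one simulation run.

    Defaults are the scaled study conditions: N = 500 beads, 55:45 A:B in
    geometric B blocks of mean 8 (contiguous heterochromatin stretches),
    reduced number density 0.2, timestep 1e-4 tau.  ``plateau_tol`` is the
    energy-slope threshold of the steady-state detector in energy units
    per tau per bead; the strict default suits fast-relaxing (weak
    affinity) runs, while slowly (logarithmically) relaxing control-
    affinity runs need a tolerance at the fluctuation scale of their
    energy trace (~5e-2) to flag the quasi-stationary window.
    """

    n_beads: int = 500
    fraction_A: float = 0.55
    params: InteractionParams = field(default_factory=InteractionParams)
    dt: float = 1e-4
    n_steps: int = 100_000
    snap_stride: int = 1000
    seed: int = 0
    cavity_radius: float | None = None
    number_density: float = 0.2
    mean_block_B: float | None = 8.0
    kT: float = 1.0
    skin: float = 0.4
    plateau_tol: float = 1e-4


@dataclass
class Trajectory:
    """Stored snapshots of a run plus bookkeeping.

    ``times`` are in tau; ``positions`` has shape (n_snapshots, N, 3);
    ``energy_per_bead`` is the total potential divided by N at each
    snapshot.  ``steady_state_start`` indexes the first snapshot of the
    detected plateau (== n_snapshots when no plateau was found, in which
    case ``steady_state`` is False and ``warnings`` records why).
    """

    times: np.ndarray
    positions: np.ndarray
    energy_per_bead: np.ndarray
    bead_type: np.ndarray
    bead_diameter: np.ndarray
    cavity_radius: float
    config: SimulationConfig
    unit_system: UnitSystem
    steady_state: bool = False
    steady_state_start: int = 0
    warnings: list = field(default_factory=list)

    @property
    def n_snapshots(self) -> int:
        return self.positions.shape[0]

    def steady_positions(self) -> np.ndarray:
        """Snapshots flagged as steady state (may be empty)."""
        return self.positions[self.steady_state_start :]

    def state_at(self, i: int) -> PolymerState:
        return PolymerState(
            self.positions[i].astype(float),
            self.bead_type,
            self.bead_diameter,
            self.cavity_radius,
            self.unit_system,
        )


def step_euler_maruyama(
    state: PolymerState,
    params: InteractionParams,
    dt: float,
    rng: np.random.Generator,
    kT: float = 1.0,
    eta: float = 1.0,
) -> PolymerState:
    """One Euler-Maruyama step; returns a new state (input untouched)."""
    from mesochrom.polymer.model import compute_forces

    if dt <= 0:
        raise ValueError("dt must be positive")
    forces, _ = compute_forces(state, params)
    gamma = 3.0 * np.pi * eta * state.bead_diameter  # 6 pi eta (sigma/2)
    mob = 1.0 / gamma
    noise = rng.standard_normal(state.positions.shape)
    new = state.copy()
    new.positions = (
        state.positions
        + forces * (mob * dt)[:, None]
        + np.sqrt(2.0 * kT * mob * dt)[:, None] * noise
    )
    if not np.all(np.isfinite(new.positions)):
        bad = int(np.where(~np.all(np.isfinite(new.positions), axis=1))[0][0])
        raise FloatingPointError(f"non-finite coordinate for bead {bad}")
    return new


def detect_plateau(
    times: np.ndarray,
    energy_per_bead: np.ndarray,
    tol: float = 1e-4,
    min_window_frac: float = 0.2,
) -> int | None:
    """Index of the first snapshot from which the energy trace is flat.

    Scans candidate window starts (earliest first); a window qualifies when
    it spans at least ``min_window_frac`` of the trace and the least-squares
    slope of energy-per-bead vs time has magnitude below ``tol`` (energy
    units per tau).  Returns None when no window qualifies.
    """
    n = len(times)
    if n < 4:
        return None
    max_start = int(np.floor(n * (1.0 - min_window_frac)))
    for start in range(0, max_start + 1, max(1, n // 20)):
        t = times[start:]
        e = energy_per_bead[start:]
        if len(t) < 4:
            break
        slope = np.polyfit(t, e, 1)[0]
        if abs(slope) < tol:
            return start
    return None


def run_simulation(
    config: SimulationConfig,
    initial_state: PolymerState | None = None,
) -> Trajectory:
    """Run a full Brownian-dynamics trajectory.

    Snapshots (including the initial state) are stored every
    ``snap_stride`` steps.  Raises :class:`FloatingPointError` on
    integration failure (non-finite coordinate), reporting the step index.
    """
    state = initial_state if initial_state is not None else build_initial_chain(
        config.n_beads,
        config.fraction_A,
        config.cavity_radius,
        seed=config.seed,
        number_density=config.number_density,
        mean_block_B=config.mean_block_B,
    )
    p = config.params
    n_snaps = config.n_steps // config.snap_stride + 1
    snapshots = np.empty((n_snaps, state.n_beads, 3))
    snap_energy = np.empty(n_snaps)
    pos = state.positions.copy()
    fail = _kernels.run_bd(
        pos,
        state.bead_diameter,
        state.is_b,
        config.n_steps,
        config.dt,
        config.kT,
        state.unit_system.reduced_viscosity,
        p.eps_vex,
        p.alpha_vex,
        p.fene_k,
        p.fene_r0,
        p.eps_HC,
        p.alpha_HC_abs,
        p.d_B_abs,
        p.eps_wall,
        p.r_cut_factor,
        state.cavity_radius,
        config.seed % (2**31),
        config.snap_stride,
        snapshots,
        snap_energy,
        config.skin,
    )
    if fail >= 0:
        raise FloatingPointError(
            f"integration failure (non-finite coordinate, bead {fail})"
        )
    times = np.arange(n_snaps) * config.snap_stride * config.dt
    e_per_bead = snap_energy / state.n_beads
    traj = Trajectory(
        times=times,
        positions=snapshots,
        energy_per_bead=e_per_bead,
        bead_type=state.bead_type,
        bead_diameter=state.bead_diameter,
        cavity_radius=state.cavity_radius,
        config=config,
        unit_system=state.unit_system,
    )
    start = detect_plateau(times, e_per_bead, tol=config.plateau_tol)
    if start is None:
        traj.steady_state = False
        traj.steady_state_start = n_snaps
        msg = "energy did not plateau within the step budget"
        traj.warnings.append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    else:
        traj.steady_state = True
        traj.steady_state_start = start
    return traj
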