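"""Trajectory persistence: HDF5 store and XYZ text export."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np

from mesochrom.polymer.model import InteractionParams
from mesochrom.polymer.simulate import SimulationConfig, Trajectory
from mesochrom.units import UnitSystem

__all__ = ["save_trajectory", "load_trajectory", "export_xyz"]

_TYPE_NAMES = np.array(["A", "B"])


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory to HDF5 (positions float32, config as attrs)."""
    cfg = asdict(traj.config)
    params = cfg.pop("params")
    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=traj.positions.astype(np.float32),
                         compression="gzip", compression_opts=4)
        f.create_dataset("times", data=traj.times)
        f.create_dataset("energy_per_bead", data=traj.energy_per_bead)
        f.create_dataset("bead_type", data=traj.bead_type)
        f.create_dataset("bead_diameter", data=traj.bead_diameter)
        f.attrs["cavity_radius"] = traj.cavity_radius
        f.attrs["steady_state"] = traj.steady_state
        f.attrs["steady_state_start"] = traj.steady_state_start
        f.attrs["warnings"] = json.dumps(traj.warnings)
        f.attrs["config"] = json.dumps(cfg)
        f.attrs["interaction_params"] = json.dumps(params)
        us = traj.unit_system
        f.attrs["unit_system"] = json.dumps(
            {"temperature_K": us.temperature_K, "viscosity_cP": us.viscosity_cP,
             "sigma_AA_nm": us.sigma_AA_nm,
             "reduced_viscosity": us.reduced_viscosity,
             "time_unit_ms": us.time_unit_ms}
        )


def load_trajectory(path: str | Path) -> Trajectory:
    with h5py.File(path, "r") as f:
        cfg = json.loads(f.attrs["config"])
        cfg["params"] = InteractionParams(**json.loads(f.attrs["interaction_params"]))
        config = SimulationConfig(**cfg)
        us = UnitSystem(**json.loads(f.attrs["unit_system"]))
        traj = Trajectory(
            times=f["times"][:],
            positions=f["positions"][:].astype(float),
            energy_per_bead=f["energy_per_bead"][:],
            bead_type=f["bead_type"][:],
            bead_diameter=f["bead_diameter"][:],
            cavity_radius=float(f.attrs["cavity_radius"]),
            config=config,
            unit_system=us,
            steady_state=bool(f.attrs["steady_state"]),
            steady_state_start=int(f.attrs["steady_state_start"]),
            warnings=json.loads(f.attrs["warnings"]),
        )
    return traj


def export_xyz(traj: Trajectory, path: str | Path, stride: int = 1) -> None:
    """Plain-text XYZ export (element A/B per bead) for visualisation."""
    with open(path, "w") as fh:
        names = _TYPE_NAMES[traj.bead_type]
        for k in range(0, traj.n_snapshots, stride):
            fh.write(f"{traj.positions.shape[1]}\n")
            fh.write(f"t={traj.times[k]:.6g} tau\n")
            for name, (x, y, z) in zip(names, traj.positions[k]):
                fh.write(f"{name} {x:.5f} {y:.5f} {z:.5f}\n")
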