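"""Dynamical and structural observables on the stored trajectories.

For every trajectory produced by 01_simulate_polymer.py this computes the
per-type mean squared displacement and overlap function, the confined
radial distribution functions, and the heterochromatin cluster statistics
(sizes, volume-equivalent diameters in nm, coordination numbers z_c and
nearest-neighbour separations), writing curves and summary tables under
results/.

Run:  python analysis/02_cluster_analysis.py
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from mesochrom.polymer.clusters import analyze_trajectory
from mesochrom.polymer.io import load_trajectory
from mesochrom.polymer.model import EC_A, HC_B
from mesochrom.polymer.observables import confined_rdf, msd, overlap_function

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = []
    for path in sorted(RESULTS.glob("traj_*.h5")):
        tag = path.stem.replace("traj_", "")
        traj = load_trajectory(path)
        if not traj.steady_state:
            print(f"{tag}: no steady state; skipping observables")
            continue
        for code, lbl in ((EC_A, "A"), (HC_B, "B")):
            for name, fn in (("msd", msd), ("overlap", overlap_function)):
                c = fn(traj, code)
                pd.DataFrame({"lag_tau": c.x, "value": c.y, "n": c.counts}
                             ).to_csv(RESULTS / f"{name}_{lbl}_{tag}.csv",
                                      index=False)
        edges = np.arange(0.05, traj.cavity_radius, 0.1)
        g = confined_rdf(traj.steady_positions()[-1], "BB",
                         traj.cavity_radius, edges, traj.bead_type)
        pd.DataFrame({"r": g.x, "g": g.y, "n": g.counts}).to_csv(
            RESULTS / f"gBB_{tag}.csv", index=False)

        summary = analyze_trajectory(traj)
        rows.append({
            "run": tag,
            "eps_HC": traj.config.params.eps_HC,
            "bond_cutoff": summary.bond_cutoff,
            "mean_cluster_count": summary.mean_cluster_count,
            "mean_size_beads": summary.mean_size_beads,
            "mean_diameter_nm": summary.mean_diameter_nm,
            "mean_zc": summary.mean_zc,
            "mean_nn_separation_nm": summary.mean_nn_separation_nm,
        })
        print(f"{tag}: {summary.mean_cluster_count:.1f} clusters, "
              f"<D> = {summary.mean_diameter_nm:.0f} nm, "
              f"<z_c> = {summary.mean_zc:.1f}, "
              f"<NN> = {summary.mean_nn_separation_nm:.0f} nm")
    if rows:
        table = pd.DataFrame(rows)
        table.to_csv(RESULTS / "cluster_summary.csv", index=False)
        (RESULTS / "cluster_summary.json").write_text(
            json.dumps(rows, indent=2))
        print(f"-> {RESULTS/'cluster_summary.csv'}")


if __name__ == "__main__":
    main()
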