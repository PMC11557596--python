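"""End-to-end phantom quantification: segmentation -> domain statistics.

Generates a two-phase heterochromatin phantom (dense spherical mesoscale
domains, skew-normal diameters with mean ~80 nm, inside a lower-density
surround), runs the threshold + watershed segmentation, and compares the
recovered effective diameters, k-NN separations, pair correlation and
coordination number against the generator's ground truth.

Run:  python analysis/03_phantom_pipeline.py [--seed S]
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from mesochrom.synth import PhantomConfig, generate_phantom
from mesochrom.tomo import (
    domain_rdf_and_zc,
    fit_skew_normal,
    hmd_threshold,
    knn_distances,
    lac_statistics,
    segment_domains,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    cfg = PhantomConfig(shape=(96, 128, 128), n_domains=120,
                        dense_lac=(0.20, 0.27), surround_lac=(0.10, 0.14))
    vol, truth = generate_phantom(cfg, seed=args.seed)
    thr = hmd_threshold(vol.data[vol.mask == 1])
    labels, table = segment_domains(vol, threshold=thr)
    table.to_csv(RESULTS / "phantom_domains.csv", index=False)

    stats = lac_statistics(vol)
    cents = table[["centroid_z_nm", "centroid_y_nm",
                   "centroid_x_nm"]].to_numpy()
    knn, _ = knn_distances(cents, k_max=10)
    fit = fit_skew_normal(table.d_eff_nm.to_numpy(), n_boot=100,
                          seed=args.seed)
    region_r = cfg.region_radius_frac * 2 * min(cfg.shape) * cfg.voxel_nm / 2
    rdf = domain_rdf_and_zc(cents, region_radius_nm=region_r,
                            mean_domain_radius_nm=table.d_eff_nm.mean() / 2)

    summary = {
        "threshold": thr,
        "n_true": len(truth),
        "n_recovered": len(table),
        "true_mean_d_nm": float(truth.diameter_nm.mean()),
        "recovered_mean_d_eff_nm": float(table.d_eff_nm.mean()),
        "mean_1nn_nm": float(knn[:, 0].mean()),
        "skewnorm_alpha": fit.alpha,
        "skewnorm_alpha_ci": fit.alpha_ci,
        "coordination_z": rdf.z,
        "hc_lac_range": [stats[1]["min"], stats[1]["max"]],
    }
    (RESULTS / "phantom_summary.json").write_text(
        json.dumps(summary, indent=2))
    print(f"threshold = {thr:.3f} 1/um; recovered {len(table)}/"
          f"{len(truth)} domains")
    print(f"mean D_eff: true {summary['true_mean_d_nm']:.1f} nm vs "
          f"recovered {summary['recovered_mean_d_eff_nm']:.1f} nm")
    print(f"mean 1-NN separation {summary['mean_1nn_nm']:.0f} nm; "
          f"skew-normal alpha {fit.alpha:.2f}; z = {rdf.z}")


if __name__ == "__main__":
    main()
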