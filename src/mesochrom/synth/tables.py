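"""Synthetic labelled feature tables emulating the four-condition design.

Four treatment classes (control, TSA, G9a, ROS) with class-mean shifts of
``effect_size`` pooled standard deviations on a configurable subset of
features, plus unit-variance Gaussian noise — the class structure that the
multiparametric PCA->LDA/Random-Forest pipeline is meant to separate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["CONDITIONS", "generate_feature_table"]

CONDITIONS = ("control", "TSA", "G9a", "ROS")

_DEFAULT_FEATURES = (
    "n_domains", "mean_d_eff_nm", "sd_d_eff_nm", "skewnorm_alpha",
    "mean_lac", "sd_lac", "lac_skewness", "foreground_volume_fraction",
    "mean_knn_1_nm", "mean_knn_5_nm", "g_first_peak_nm", "mean_zc",
)


def generate_feature_table(
    n_per_class: int = 25,
    effect_size: float = 2.0,
    seed: int = 0,
    feature_names: tuple[str, ...] = _DEFAULT_FEATURES,
    n_informative: int | None = None,
) -> pd.DataFrame:
    """Labelled per-region feature table with planted class structure.

    Each class mean is shifted along a class-specific random direction on
    the first ``n_informative`` features (all by default) by
    ``effect_size`` pooled SDs; remaining features are pure noise.
    ``effect_size = 0`` gives an exchangeable null.  Deterministic per seed.
    """
    if n_per_class < 5:
        raise ValueError("need at least 5 rows per class")
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    rng = np.random.default_rng(seed)
    p = len(feature_names)
    k = p if n_informative is None else min(n_informative, p)
    rows = []
    labels = []
    for ci, cond in enumerate(CONDITIONS):
        direction = np.zeros(p)
        d = rng.normal(size=k)
        direction[:k] = d / np.linalg.norm(d)
        mean = effect_size * direction
        rows.append(rng.normal(mean, 1.0, size=(n_per_class, p)))
        labels += [cond] * n_per_class
    table = pd.DataFrame(np.vstack(rows), columns=list(feature_names))
    table["label"] = labels
    return table
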