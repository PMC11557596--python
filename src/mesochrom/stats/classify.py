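"""Multiparametric classification of treatment conditions.

The pipeline mirrors standard multivariate morphometry practice: features
are z-scored, reduced by PCA (first 12 components by default), and the PC
scores used as discriminant variables in LDA trained on a stratified 60%
split; held-out accuracy and per-class 95% confidence ellipses (multivariate
t) in LD space summarise class separability.  A Random-Forest classifier,
tuned over its tree count, provides a nonlinear validation and selects the
features whose permutation importance exceeds 40% of the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

__all__ = ["LDAResult", "RFResult", "lda_pipeline",
           "rf_validate_and_select", "confidence_ellipse_t",
           "mann_whitney_u"]


@dataclass
class ConfidenceEllipse:
    """95% multivariate-t ellipse of one class in the first two LDs."""

    label: str
    center: np.ndarray
    width: float       # full axis lengths
    height: float
    angle_deg: float


@dataclass
class LDAResult:
    projection: pd.DataFrame       # LD scores + label for held-out data
    train_projection: pd.DataFrame
    accuracy: float
    per_class_accuracy: dict[str, float]
    ellipses: list[ConfidenceEllipse]
    n_pcs: int
    pca_explained_variance: np.ndarray
    regularized: bool = False


def confidence_ellipse_t(scores: np.ndarray, level: float = 0.95
                         ) -> tuple[np.ndarray, float, float, float]:
    """Ellipse parameters covering ``level`` mass of a fitted multivariate
    t (Hotelling small-sample scaling) in 2D.

    Returns (center, width, height, angle_deg); width/height are full axis
    lengths along the covariance eigenvectors.
    """
    x = np.asarray(scores, dtype=float)
    n, p = x.shape
    if n < 3 or p != 2:
        raise ValueError("need >= 3 points in 2D")
    center = x.mean(axis=0)
    cov = np.cov(x, rowvar=False)
    # multivariate-t radius: r^2 = p (n-1)/(n-p) F_{p, n-p}(level)
    fq = sps.f.ppf(level, p, n - p)
    r2 = p * (n - 1) / (n - p) * fq
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    width, height = 2.0 * np.sqrt(np.maximum(evals, 0) * r2)
    angle = float(np.rad2deg(np.arctan2(evecs[1, 0], evecs[0, 0])))
    return center, float(width), float(height), angle


def _stratified_split(x, y, train_fraction, seed, max_tries=20):
    """Stratified split; resplits until every class appears in training."""
    classes = np.unique(y)
    for t in range(max_tries):
        xtr, xte, ytr, yte = train_test_split(
            x, y, train_size=train_fraction, random_state=seed + t,
            stratify=y)
        if len(np.unique(ytr)) == len(classes):
            return xtr, xte, ytr, yte
    raise RuntimeError("could not produce a split covering every class")


def lda_pipeline(features: pd.DataFrame, train_fraction: float = 0.6,
                 n_pcs: int = 12, seed: int = 0,
                 label_col: str = "label") -> LDAResult:
    """PCA -> LDA classification of labelled feature rows.

    PCA (and the z-scoring) are fit on the training split only; LDA runs
    on the PC scores; accuracy is evaluated on the held-out split.
    Singular within-class scatter triggers shrinkage regularisation
    (reported via ``regularized``).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    y = features[label_col].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    x = features.drop(columns=[label_col]).select_dtypes("number")
    x = x.dropna(axis=1, how="any").to_numpy(dtype=float)
    n_pcs = min(n_pcs, x.shape[1], int(x.shape[0] * train_fraction) - 1)

    xtr, xte, ytr, yte = _stratified_split(x, y, train_fraction, seed)
    scaler = StandardScaler().fit(xtr)
    pca = PCA(n_components=n_pcs, random_state=seed).fit(
        scaler.transform(xtr))
    ztr = pca.transform(scaler.transform(xtr))
    zte = pca.transform(scaler.transform(xte))

    regularized = False
    lda = LinearDiscriminantAnalysis()
    try:
        lda.fit(ztr, ytr)
    except np.linalg.LinAlgError:
        regularized = True
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        lda.fit(ztr, ytr)
    pred = lda.predict(zte)
    accuracy = float(np.mean(pred == yte))
    per_class = {
        str(c): float(np.mean(pred[yte == c] == c))
        for c in np.unique(yte)
    }

    def proj_frame(z, yy):
        ld = lda.transform(z)
        cols = {f"LD{i + 1}": ld[:, i] for i in range(ld.shape[1])}
        cols[label_col] = yy
        return pd.DataFrame(cols)

    train_proj = proj_frame(ztr, ytr)
    test_proj = proj_frame(zte, yte)
    ellipses = []
    if train_proj.shape[1] - 1 >= 2:
        for c in np.unique(ytr):
            pts = train_proj.loc[train_proj[label_col] == c,
                                 ["LD1", "LD2"]].to_numpy()
            if len(pts) >= 3:
                center, w, h, ang = confidence_ellipse_t(pts)
                ellipses.append(ConfidenceEllipse(str(c), center, w, h, ang))
    return LDAResult(test_proj, train_proj, accuracy, per_class, ellipses,
                     n_pcs, pca.explained_variance_ratio_, regularized)


@dataclass
class RFResult:
    accuracy: float
    n_trees: int
    importances: pd.Series
    selected_features: list[str]
    mode: str


def rf_validate_and_select(features: pd.DataFrame, seed: int = 0,
                           train_fraction: float = 0.6,
                           tree_grid: tuple[int, ...] = (50, 100, 200, 400),
                           label_col: str = "label",
                           importance: str = "permutation") -> RFResult:
    """Random-Forest validation with importance-based feature selection.

    The tree count is tuned on out-of-bag accuracy; features scoring
    above 40% of the maximum importance are retained.  ``importance``
    selects permutation importance (default) or the forest's impurity
    importances.  Deterministic for a given seed.
    """
    y = features[label_col].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    xdf = features.drop(columns=[label_col]).select_dtypes("number")
    xdf = xdf.dropna(axis=1, how="any")
    x = xdf.to_numpy(dtype=float)
    xtr, xte, ytr, yte = _stratified_split(x, y, train_fraction, seed)

    best_nt, best_oob = None, -np.inf
    for nt in tree_grid:
        rf = RandomForestClassifier(n_estimators=nt, oob_score=True,
                                    random_state=seed, n_jobs=1)
        rf.fit(xtr, ytr)
        if rf.oob_score_ > best_oob:
            best_oob, best_nt = rf.oob_score_, nt
    rf = RandomForestClassifier(n_estimators=best_nt, random_state=seed,
                                n_jobs=1)
    rf.fit(xtr, ytr)
    accuracy = float(rf.score(xte, yte))

    if importance == "permutation":
        imp = permutation_importance(rf, xte, yte, n_repeats=10,
                                     random_state=seed,
                                     n_jobs=1).importances_mean
    else:
        imp = rf.feature_importances_
    imp = pd.Series(imp, index=xdf.columns)
    mx = imp.max()
    if mx > 0:
        selected = list(imp.index[imp > 0.4 * mx])
    else:
        selected = []
    return RFResult(accuracy, int(best_nt), imp, selected, importance)


def mann_whitney_u(sample: np.ndarray, control: np.ndarray,
                   alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U statistic (of ``sample`` vs ``control``) and p-value.

    Exact distribution for small samples without ties, normal
    approximation otherwise (scipy's default policy)."""
    u, p = sps.mannwhitneyu(sample, control, alternative=alternative)
    return float(u), float(p)
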