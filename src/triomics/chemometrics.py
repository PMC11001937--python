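"""Latent-variable chemometrics: UV scaling, PCA, PLS-DA, and a
QC-dispersion diagnostic.

R2 follows the chemometrics convention: for PCA the fraction of data
variance each component explains; for PLS-DA the fraction of the
dummy-coded class matrix explained.  Q2 = 1 - PRESS/TSS estimated by
stratified venetian-blinds cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression


@dataclass
class LatentModel:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    r2: np.ndarray  # per-component explained-variance fractions
    q2: float | None = None
    labels: pd.Series | None = None
    kind: str = "pca"


def uv_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Unit-variance autoscale: each feature to mean 0, sd 1 (ddof=1).
    Zero-variance features are dropped with a warning."""
    sd = matrix.std(ddof=1)
    const = sd[(sd == 0) | sd.isna()].index
    if len(const):
        warnings.warn(f"dropping {len(const)} constant feature(s)", stacklevel=2)
        matrix = matrix.drop(columns=const)
        sd = sd.drop(const)
    return (matrix - matrix.mean()) / sd


def _fix_signs(scores: np.ndarray, loadings: np.ndarray) -> None:
    """Deterministic orientation: the largest-|loading| entry of each
    component is made positive."""
    for h in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, h])))
        if loadings[j, h] < 0:
            loadings[:, h] *= -1
            scores[:, h] *= -1


def pca(matrix: pd.DataFrame, ncomp: int = 2) -> LatentModel:
    """Principal component analysis by SVD of the column-centered matrix."""
    n, p = matrix.shape
    if ncomp > min(n - 1, p):
        raise ValueError(f"ncomp={ncomp} exceeds min(n_samples-1, n_features)")
    X = matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :ncomp] * s[:ncomp]
    loadings = Vt[:ncomp].T.copy()
    _fix_signs(scores, loadings)
    total = (Xc**2).sum()
    r2 = (s[:ncomp] ** 2) / total if total > 0 else np.zeros(ncomp)
    comp = [f"PC{i + 1}" for i in range(ncomp)]
    return LatentModel(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp),
        loadings=pd.DataFrame(loadings, index=matrix.columns, columns=comp),
        r2=r2,
        kind="pca",
    )


def _dummy(labels: pd.Series) -> tuple[np.ndarray, list]:
    classes = sorted(pd.unique(labels))
    Y = np.zeros((len(labels), len(classes)))
    for j, c in enumerate(classes):
        Y[np.asarray(labels) == c, j] = 1.0
    return Y, classes


def venetian_blinds(labels: pd.Series, folds: int) -> np.ndarray:
    """Fold assignment cycling through samples within each class stratum."""
    labels = pd.Series(np.asarray(labels))
    fold = np.zeros(len(labels), dtype=int)
    for c in sorted(labels.unique()):
        idx = np.flatnonzero(labels.to_numpy() == c)
        fold[idx] = np.arange(len(idx)) % folds
    return fold


def plsda(
    matrix: pd.DataFrame,
    labels,
    ncomp: int = 2,
    folds: int = 7,
    repeats: int = 1,
    seed: int = 0,
) -> LatentModel:
    """PLS discriminant analysis on a dummy-coded class response.

    Components maximize covariance with the centered dummy matrix
    (NIPALS).  Q2 is 1 - PRESS/TSS over stratified venetian-blind folds;
    with ``repeats > 1`` the sample order within strata is reshuffled per
    repeat and the mean Q2 returned.
    """
    labels = pd.Series(np.asarray(labels), index=matrix.index)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least two classes")
    if min((labels == c).sum() for c in classes) < folds:
        raise ValueError("every class needs at least `folds` members")
    X = matrix.to_numpy(dtype=float)
    Y, _ = _dummy(labels)

    pls = PLSRegression(n_components=ncomp, scale=False)
    pls.fit(X, Y)
    T, Q = pls.x_scores_, pls.y_loadings_
    Yc = Y - Y.mean(axis=0)
    tss = (Yc**2).sum()
    r2 = np.empty(ncomp)
    prev = 0.0
    for h in range(1, ncomp + 1):
        resid = Yc - T[:, :h] @ Q[:, :h].T
        cum = 1.0 - (resid**2).sum() / tss
        r2[h - 1] = cum - prev
        prev = cum

    rng = np.random.default_rng(seed)
    q2s = []
    for rep in range(repeats):
        order = np.arange(len(labels))
        if rep > 0:
            order = rng.permutation(order)
        fold = np.empty(len(labels), dtype=int)
        fold[order] = venetian_blinds(labels.iloc[order], folds)
        press = tss_cv = 0.0
        for f in range(folds):
            tr, te = fold != f, fold == f
            m = PLSRegression(n_components=ncomp, scale=False)
            m.fit(X[tr], Y[tr])
            press += ((Y[te] - m.predict(X[te])) ** 2).sum()
            tss_cv += ((Y[te] - Y[tr].mean(axis=0)) ** 2).sum()
        q2s.append(1.0 - press / tss_cv)
    q2 = float(np.mean(q2s))

    scores = T.copy()
    loadings = pls.x_loadings_.copy()
    _fix_signs(scores, loadings)
    comp = [f"LV{i + 1}" for i in range(ncomp)]
    return LatentModel(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp),
        loadings=pd.DataFrame(loadings, index=matrix.columns, columns=comp),
        r2=r2,
        q2=q2,
        labels=labels,
        kind="plsda",
    )


def qc_dispersion(model: LatentModel, roles: pd.Series) -> float:
    """Tightness of the QC cluster in score space.

    Returns mean squared distance of QC scores to the QC centroid divided
    by the same quantity for study samples; well below 1 means the QCs
    cluster tightly relative to biological spread.
    """
    roles = pd.Series(np.asarray(roles), index=model.scores.index)
    qc = model.scores.loc[roles == "qc"].to_numpy()
    study = model.scores.loc[roles == "study"].to_numpy()
    if len(qc) < 2:
        raise ValueError("qc_dispersion needs at least 2 QC scores")
    msd = lambda A: float(((A - A.mean(axis=0)) ** 2).sum(axis=1).mean())
    denom = msd(study)
    return msd(qc) / denom if denom > 0 else np.inf
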