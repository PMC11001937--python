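"""Pooled-QC normalization: intra-batch QC-SVRC, inter-batch QC-Norm,
and KNN missing-value imputation.

QC-SVRC fits, per feature and batch, a support-vector regression (radial
basis kernel) of interspersed-QC intensity against injection order and
divides every injection by the predicted drift relative to the batch QC
median — a multiplicative drift model.  QC-Norm then equalizes the
per-feature QC medians across batches by scaling each batch to the grand
QC median.  Hyperparameters are chosen per curve by leave-one-QC-out
error over a small fixed grid, since the drift is smooth and the QC
series short.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .qa import interspersed_qc_mask

MIN_QCS = 5

# grid: cost in decades, epsilon as fractions of the QC median absolute
# deviation.  The MAD mixes drift amplitude with noise, so the grid
# reaches well below 1 MAD and leave-one-QC-out picks the tube width.
_C_GRID = (1.0, 10.0, 100.0)
_EPS_MAD = (0.05, 0.1, 0.25, 0.5, 1.0)


class DriftError(ValueError):
    pass


@dataclass
class _Curve:
    svr: SVR | None
    x_lo: float
    x_hi: float
    n_inj: int
    reference: float
    flat: bool = False

    def predict(self, orders: np.ndarray) -> np.ndarray:
        if self.flat or self.svr is None:
            return np.full(len(orders), self.reference)
        x = np.clip(orders, self.x_lo, self.x_hi)  # nearest-edge outside range
        return self.svr.predict((x / self.n_inj).reshape(-1, 1))


@dataclass
class DriftModel:
    """Fitted QC drift curves, one per feature per batch."""

    curves: dict[tuple[str, int], _Curve] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def _fit_one(x: np.ndarray, y: np.ndarray, n_inj: int) -> tuple[SVR | None, bool]:
    """Leave-one-QC-out grid selection; returns (svr, flat_fallback)."""
    xs = (x / n_inj).reshape(-1, 1)
    mad = np.median(np.abs(y - np.median(y)))
    if mad == 0:
        return None, True  # constant QCs: identity correction
    best, best_err = None, np.inf
    for c_rel in _C_GRID:
        for e_mad in _EPS_MAD:
            eps = e_mad * mad
            C = c_rel * max(np.abs(y).max(), 1e-12)
            errs = []
            for i in range(len(y)):
                keep = np.arange(len(y)) != i
                m = SVR(kernel="rbf", C=C, epsilon=eps, gamma="scale")
                m.fit(xs[keep], y[keep])
                errs.append((m.predict(xs[[i]])[0] - y[i]) ** 2)
            err = float(np.mean(errs))
            if err < best_err:
                best_err, best = err, (C, eps)
    m = SVR(kernel="rbf", C=best[0], epsilon=best[1], gamma="scale")
    m.fit(xs, y)
    # curve must stay strictly positive over the batch's injection range
    grid = np.linspace(x.min(), x.max(), 50) / n_inj
    if np.any(m.predict(grid.reshape(-1, 1)) <= 0):
        return None, True
    return m, False


def qc_svrc_fit(
    batch_matrix: pd.DataFrame,
    qc_mask: np.ndarray,
    injection_orders: np.ndarray,
) -> DriftModel:
    """Fit per-feature drift curves to interspersed QCs of one batch.

    ``qc_mask`` marks the interspersed QC rows of ``batch_matrix``;
    ``injection_orders`` gives the order of every row.  Features whose
    QC series is constant, too sparse, or yields a non-positive curve
    fall back to a flat batch-median model and are flagged.
    """
    injection_orders = np.asarray(injection_orders, dtype=float)
    if qc_mask.sum() < MIN_QCS:
        raise DriftError(
            f"QC-SVRC needs at least {MIN_QCS} interspersed QCs per batch, "
            f"found {int(qc_mask.sum())}"
        )
    n_inj = int(injection_orders.max())
    model = DriftModel()
    batch_id = 0
    x_all = injection_orders[qc_mask]
    for f in batch_matrix.columns:
        y_all = batch_matrix.loc[qc_mask, f].to_numpy(dtype=float)
        ok = ~np.isnan(y_all)
        x, y = x_all[ok], y_all[ok]
        ref = float(np.median(y)) if len(y) else np.nan
        if len(y) < MIN_QCS or not np.isfinite(ref) or ref <= 0:
            safe_ref = ref if np.isfinite(ref) and ref > 0 else 1.0
            model.curves[(f, batch_id)] = _Curve(None, 0, n_inj, n_inj, safe_ref, True)
            model.flags.append(f"{f}: insufficient QC signal, flat model")
            continue
        svr, flat = _fit_one(x, y, n_inj)
        if flat and not np.all(y == y[0]):
            model.flags.append(f"{f}: non-positive or degenerate fit, flat model")
        model.curves[(f, batch_id)] = _Curve(svr, x.min(), x.max(), n_inj, ref, flat)
    return model


def qc_svrc_apply(
    batch_matrix: pd.DataFrame,
    model: DriftModel,
    injection_orders: np.ndarray,
) -> pd.DataFrame:
    """Divide each intensity by predicted-drift / QC-reference."""
    injection_orders = np.asarray(injection_orders, dtype=float)
    out = batch_matrix.copy()
    for f in batch_matrix.columns:
        curve = model.curves.get((f, 0))
        if curve is None:
            raise DriftError(f"drift model does not cover feature {f}")
        pred = curve.predict(injection_orders)
        out[f] = batch_matrix[f].to_numpy() / (pred / curve.reference)
    return out


def correct_batches(
    matrix: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, dict[int, DriftModel]]:
    """QC-SVRC every batch of a combined matrix; returns corrected matrix
    and the per-batch models."""
    m = meta.set_index("sample_id").loc[matrix.index]
    qc = interspersed_qc_mask(meta, matrix)
    pieces, models = [], {}
    for batch in sorted(m["batch"].unique()):
        in_b = (m["batch"] == batch).to_numpy()
        sub = matrix.iloc[in_b]
        orders = m.loc[in_b, "injection_order"].to_numpy()
        model = qc_svrc_fit(sub, qc[in_b], orders)
        pieces.append(qc_svrc_apply(sub, model, orders))
        models[batch] = model
    out = pd.concat(pieces).loc[matrix.index]
    return out, models


def qc_norm(
    matrix: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Inter-batch scaling: per feature, each batch is multiplied by
    (grand median of interspersed-QC intensities) / (batch QC median), so
    QC medians agree across batches afterwards.  Features with a
    non-positive batch QC median are excluded and flagged."""
    m = meta.set_index("sample_id").loc[matrix.index]
    qc = interspersed_qc_mask(meta, matrix)
    if qc.sum() == 0:
        raise DriftError("QC-Norm requires interspersed QCs")
    batches = sorted(m["batch"].unique())
    grand = matrix.iloc[qc].median(skipna=True)
    out = matrix.copy()
    dropped = []
    for f in matrix.columns:
        scales = {}
        for batch in batches:
            sel = qc & (m["batch"] == batch).to_numpy()
            med = matrix.loc[sel, f].median(skipna=True)
            if not np.isfinite(med) or med <= 0:
                scales = None
                break
            scales[batch] = grand[f] / med
        if scales is None:
            dropped.append(f)
            continue
        for batch, s in scales.items():
            rows = (m["batch"] == batch).to_numpy()
            out.loc[rows, f] = matrix.loc[rows, f] * s
    if dropped:
        out = out.drop(columns=dropped)
    return out, dropped


def knn_impute(matrix: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Impute missing entries with the mean of the k nearest samples.

    Distances are Euclidean over shared observed features after per-
    feature unit-variance scaling; observed entries are returned
    untouched.  Mirrors targeted-panel practice where a single analyte
    (e.g. GABA) is undetected in some samples.
    """
    from sklearn.impute import KNNImputer

    if k >= matrix.shape[0]:
        raise ValueError("k must be smaller than the number of samples")
    if matrix.isna().all(axis=0).any():
        bad = matrix.columns[matrix.isna().all(axis=0)].tolist()
        raise ValueError(f"feature(s) missing in every sample: {bad}")
    if matrix.isna().all(axis=1).any():
        bad = matrix.index[matrix.isna().all(axis=1)].tolist()
        raise ValueError(f"sample(s) with no observed values: {bad}")
    if not matrix.isna().any().any():
        return matrix.copy()
    mu = matrix.mean(skipna=True)
    sd = matrix.std(skipna=True, ddof=1).replace(0, 1.0).fillna(1.0)
    scaled = (matrix - mu) / sd
    imp = KNNImputer(n_neighbors=k, weights="uniform")
    filled = pd.DataFrame(imp.fit_transform(scaled), index=matrix.index,
                          columns=matrix.columns)
    return filled * sd + mu


def normalize_pipeline(
    matrix: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """QC-SVRC per batch then QC-Norm across batches."""
    corrected, models = correct_batches(matrix, meta)
    unified, dropped = qc_norm(corrected, meta)
    return unified, {"models": models, "qcnorm_dropped": dropped}
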