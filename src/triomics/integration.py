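"""Multiblock sparse PLS-DA for multi-omics integration.

Several data blocks measured on the same samples (metabolites, ASVs,
KOs) are integrated against a class outcome by iteratively maximizing
the design-weighted sum of covariances between block scores and the
dummy-outcome score, with per-block sparsity: on every component each
block retains exactly ``keepX`` variables via soft-thresholding of its
loading vector.  Blocks are deflated component-wise, so successive
scores within a block are orthogonal.

Performance is assessed by stratified k-fold cross-validation repeated
with reshuffled folds (majority vote over per-block nearest-centroid
calls), per-block one-vs-all AUROC from the score-space class
predictions, a similarity matrix over selected variables (the circos
construction: products of variable-component correlations), and a
clustered image map with Euclidean distance and complete linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st

MAX_ITER = 500
TOL = 1e-6


@dataclass
class MultiblockModel:
    block_names: list
    classes: list
    ncomp: int
    keepX: dict  # block -> list per component
    design: pd.DataFrame  # block x block weights (plus implicit 1 to outcome)
    scores: dict  # block -> DataFrame (n x ncomp)
    loadings: dict  # block -> DataFrame (p x ncomp), sparse weight vectors
    defl_loadings: dict  # block -> (p x ncomp) regression loadings for deflation
    selected: dict  # block -> list[set] per component
    y_scores: np.ndarray
    y_weights: np.ndarray  # classes x ncomp
    x_means: dict
    x_sds: dict
    y_dummy: pd.DataFrame
    sample_ids: pd.Index
    labels: pd.Series
    n_iter: list = field(default_factory=list)

    def block_score_correlations(self, comp: int = 0) -> pd.DataFrame:
        cols = {b: self.scores[b].iloc[:, comp] for b in self.block_names}
        return pd.DataFrame(cols).corr()

    def rotation(self, block: str) -> np.ndarray:
        """Direct projection matrix R = A (P'A)^-1 mapping preprocessed
        data to scores, absorbing the deflation sequence."""
        A = self.loadings[block].to_numpy()
        P = self.defl_loadings[block]
        return A @ np.linalg.inv(P.T @ A)

    def transform(self, blocks: dict) -> dict:
        out = {}
        for b in self.block_names:
            X = blocks[b].to_numpy(dtype=float)
            Xs = (X - self.x_means[b]) / self.x_sds[b]
            out[b] = Xs @ self.rotation(b)
        return out


def _dummy(labels: pd.Series) -> tuple[np.ndarray, list]:
    classes = sorted(pd.unique(labels))
    Y = np.zeros((len(labels), len(classes)))
    for j, c in enumerate(classes):
        Y[np.asarray(labels) == c, j] = 1.0
    return Y, classes


def _soft_keep(w: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold so exactly ``keep`` entries are nonzero; ties at the
    threshold are broken by variable index (stable order)."""
    p = w.size
    if keep >= p:
        return w.copy()
    order = np.argsort(-np.abs(w), kind="stable")
    thr = np.abs(w[order[keep]])
    out = np.zeros_like(w)
    kept = order[:keep]
    shrunk = np.abs(w[kept]) - thr
    shrunk[shrunk <= 0] = 1e-12  # tie at the threshold: keep, barely
    out[kept] = np.sign(w[kept]) * shrunk
    return out


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def fit_block_splsda(
    blocks: dict,
    labels,
    design: pd.DataFrame | float = 1.0,
    ncomp: int = 2,
    keepX: int | dict = 25,
    scale: bool = True,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> MultiblockModel:
    """Fit the multiblock sparse discriminant model.

    ``blocks`` maps block name -> samples x features DataFrame (shared
    sample index).  ``design`` is either a scalar off-diagonal weight for
    the full design (default 1: every block connected to every other and
    to the outcome) or a block x block DataFrame.  ``keepX`` is the
    number of variables each block retains per component (int, or dict
    block -> int or list per component).
    """
    names = list(blocks)
    ids = blocks[names[0]].index
    for b in names[1:]:
        if not blocks[b].index.equals(ids):
            raise ValueError("blocks must share an identical sample index")
    labels = pd.Series(np.asarray(labels), index=ids)
    Y, classes = _dummy(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")

    if isinstance(design, (int, float)):
        D = pd.DataFrame(float(design), index=names, columns=names)
        np.fill_diagonal(D.values, 0.0)
    else:
        D = design.loc[names, names].astype(float)

    kx = {}
    for b in names:
        p = blocks[b].shape[1]
        if isinstance(keepX, dict):
            v = keepX[b]
            kx[b] = list(v) if not np.isscalar(v) else [int(v)] * ncomp
        else:
            kx[b] = [int(keepX)] * ncomp
        if any(k > p for k in kx[b]):
            raise ValueError(f"keepX exceeds width of block {b!r} ({p})")

    X, means, sds = {}, {}, {}
    for b in names:
        M = blocks[b].to_numpy(dtype=float)
        mu = M.mean(axis=0)
        sd = M.std(axis=0, ddof=1) if scale else np.ones(M.shape[1])
        sd = np.where(sd > 0, sd, 1.0)
        X[b] = (M - mu) / sd
        means[b], sds[b] = mu, sd
    Yc = Y - Y.mean(axis=0)

    n = len(ids)
    A = {b: np.zeros((X[b].shape[1], ncomp)) for b in names}
    P = {b: np.zeros((X[b].shape[1], ncomp)) for b in names}
    T = {b: np.zeros((n, ncomp)) for b in names}
    U = np.zeros((n, ncomp))
    C = np.zeros((len(classes), ncomp))
    selected = {b: [] for b in names}
    n_iters = []

    Xd = {b: X[b].copy() for b in names}
    Yd = Yc.copy()
    for h in range(ncomp):
        # deterministic init: dominant covariance direction with the outcome
        a = {}
        for b in names:
            M = Xd[b].T @ Yd
            u_, s_, vt_ = np.linalg.svd(M, full_matrices=False)
            v = u_[:, 0]
            j = int(np.argmax(np.abs(v)))
            a[b] = _unit(v if v[j] >= 0 else -v)
        c = _unit(Yd.T @ Xd[names[0]] @ a[names[0]])
        t = {b: Xd[b] @ a[b] for b in names}
        u = Yd @ c

        it = 0
        for it in range(1, max_iter + 1):
            delta = 0.0
            for b in names:
                target = u.copy()  # outcome always weighted 1
                for b2 in names:
                    if b2 != b and D.loc[b, b2] != 0:
                        target = target + D.loc[b, b2] * t[b2]
                w = Xd[b].T @ target
                w = _soft_keep(w, kx[b][h])
                w = _unit(w)
                delta = max(delta, np.abs(w - a[b]).max())
                a[b] = w
                t[b] = Xd[b] @ w
            c_new = _unit(Yd.T @ sum(t[b] for b in names))
            delta = max(delta, np.abs(c_new - c).max())
            c = c_new
            u = Yd @ c
            if delta < tol:
                break
        else:
            raise RuntimeError(
                f"component {h + 1} did not converge in {max_iter} iterations "
                f"(last change {delta:.2e})"
            )
        n_iters.append(it)

        for b in names:
            tb = t[b]
            denom = float(tb @ tb)
            pb = Xd[b].T @ tb / denom if denom > 0 else np.zeros(Xd[b].shape[1])
            Xd[b] = Xd[b] - np.outer(tb, pb)
            A[b][:, h] = a[b]
            P[b][:, h] = pb
            T[b][:, h] = tb
            selected[b].append(
                set(blocks[b].columns[np.flatnonzero(a[b])])
            )
        du = float(u @ u)
        if du > 0:
            Yd = Yd - np.outer(u, Yd.T @ u / du)
        U[:, h] = u
        C[:, h] = c

    comp = [f"comp{i + 1}" for i in range(ncomp)]
    return MultiblockModel(
        block_names=names,
        classes=classes,
        ncomp=ncomp,
        keepX=kx,
        design=D,
        scores={b: pd.DataFrame(T[b], index=ids, columns=comp) for b in names},
        loadings={
            b: pd.DataFrame(A[b], index=blocks[b].columns, columns=comp)
            for b in names
        },
        defl_loadings=P,
        selected=selected,
        y_scores=U,
        y_weights=C,
        x_means=means,
        x_sds=sds,
        y_dummy=pd.DataFrame(Y, index=ids, columns=classes),
        sample_ids=ids,
        labels=labels,
        n_iter=n_iters,
    )


# ------------------------------------------------------------------ prediction


def _predict_classes(
    model: MultiblockModel, blocks: dict, ncomp: int | None = None
) -> pd.Series:
    """Majority vote over per-block nearest-centroid calls in score
    space; ties resolved toward the alphabetically first class."""
    ncomp = ncomp or model.ncomp
    new_scores = model.transform(blocks)
    votes = []
    for b in model.block_names:
        train = model.scores[b].to_numpy()[:, :ncomp]
        cents = {
            c: train[np.asarray(model.labels) == c].mean(axis=0)
            for c in model.classes
        }
        S = new_scores[b][:, :ncomp]
        d = np.stack(
            [np.linalg.norm(S - cents[c], axis=1) for c in model.classes], axis=1
        )
        votes.append(np.asarray(model.classes)[d.argmin(axis=1)])
    votes = np.stack(votes, axis=1)
    out = []
    for row in votes:
        vals, cnt = np.unique(row, return_counts=True)
        out.append(sorted(vals[cnt == cnt.max()])[0])
    return pd.Series(out, index=blocks[model.block_names[0]].index)


def perf_cv(
    blocks: dict,
    labels,
    design: pd.DataFrame | float = 1.0,
    ncomp: int = 2,
    keepX: int | dict = 25,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated stratified k-fold classification error of the multiblock
    model (majority vote); mean and sd over repeats, per component."""
    names = list(blocks)
    ids = blocks[names[0]].index
    labels = pd.Series(np.asarray(labels), index=ids)
    counts = labels.value_counts()
    if counts.min() < folds:
        raise ValueError(
            f"smallest class ({counts.min()}) smaller than folds={folds}"
        )
    rng = np.random.default_rng(seed)
    err = np.zeros((repeats, ncomp))
    for rep in range(repeats):
        fold = np.empty(len(ids), dtype=int)
        for c in counts.index:
            idx = np.flatnonzero(labels.to_numpy() == c)
            idx = rng.permutation(idx)
            fold[idx] = np.arange(len(idx)) % folds
        wrong = np.zeros(ncomp)
        for f in range(folds):
            tr = fold != f
            te = fold == f
            model = fit_block_splsda(
                {b: blocks[b].iloc[tr] for b in names},
                labels.iloc[tr],
                design=design,
                ncomp=ncomp,
                keepX=keepX,
            )
            for h in range(1, ncomp + 1):
                pred = _predict_classes(
                    model, {b: blocks[b].iloc[te] for b in names}, ncomp=h
                )
                wrong[h - 1] += (pred.to_numpy() != labels.iloc[te].to_numpy()).sum()
        err[rep] = wrong / len(ids)
    comp = [f"comp{i + 1}" for i in range(ncomp)]
    return pd.DataFrame(
        {"mean_error": err.mean(axis=0), "sd_error": err.std(axis=0, ddof=1)
         if repeats > 1 else 0.0},
        index=comp,
    )


def auroc(scores, positive_mask) -> float:
    """Mann-Whitney AUC with mid-rank tie handling."""
    s = np.asarray(scores, dtype=float)
    pos = np.asarray(positive_mask, dtype=bool)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be non-empty")
    r = st.rankdata(s)
    return float((r[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auroc_block(model: MultiblockModel, block: str, contrast: str) -> float:
    """One-vs-all AUROC of a block's class prediction for ``contrast``.

    The continuous score is the least-squares prediction of the contrast
    dummy column from the block's component scores.
    """
    if contrast not in model.classes:
        raise ValueError(f"unknown class {contrast!r}")
    T = model.scores[block].to_numpy()
    y = model.y_dummy[contrast].to_numpy()
    Ta = np.column_stack([np.ones(len(T)), T])
    coef, *_ = np.linalg.lstsq(Ta, y, rcond=None)
    yhat = Ta @ coef
    return auroc(yhat, y == 1)


def auroc_table(model: MultiblockModel) -> pd.DataFrame:
    rows = []
    for b in model.block_names:
        for c in model.classes:
            rows.append(
                {"block": b, "contrast": f"{c} vs Others",
                 "auc": auroc_block(model, b, c)}
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ similarity / CIM


def selected_union(model: MultiblockModel, block: str) -> list:
    out: list = []
    for s in model.selected[block]:
        for v in sorted(s):
            if v not in out:
                out.append(v)
    return out


def similarity_matrix(
    model: MultiblockModel,
    blocks: dict,
    cutoff: float = 0.65,
    include_within: bool = False,
) -> pd.DataFrame:
    """Signed associations between selected variables above ``cutoff``.

    Each selected variable is projected onto the components as its
    correlation with the averaged block scores; the association of a pair
    is the inner product of their projection vectors (the circos-plot
    construction).  Only |value| > cutoff rows are returned; the diagonal
    is excluded and, by default, so are within-block pairs.
    """
    avg = sum(model.scores[b].to_numpy() for b in model.block_names) / len(
        model.block_names
    )
    coords = {}
    for b in model.block_names:
        Xs = (blocks[b].to_numpy(dtype=float) - model.x_means[b]) / model.x_sds[b]
        cols = list(blocks[b].columns)
        for v in selected_union(model, b):
            x = Xs[:, cols.index(v)]
            coords[(b, v)] = np.array(
                [np.corrcoef(x, avg[:, h])[0, 1] for h in range(model.ncomp)]
            )
    keys = sorted(coords)
    rows = []
    for i, k1 in enumerate(keys):
        for k2 in keys[i + 1 :]:
            if not include_within and k1[0] == k2[0]:
                continue
            sim = float(coords[k1] @ coords[k2])
            if abs(sim) > cutoff:
                rows.append(
                    {"block1": k1[0], "var1": k1[1], "block2": k2[0],
                     "var2": k2[1], "similarity": sim}
                )
    return pd.DataFrame(rows, columns=["block1", "var1", "block2", "var2",
                                       "similarity"])


@dataclass
class CIMResult:
    matrix: pd.DataFrame  # reordered samples x variables
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list
    col_order: list
    row_ids: list
    col_ids: list

    def cut_rows(self, k: int) -> pd.Series:
        """Cluster labels from cutting the sample dendrogram at k
        clusters, indexed by the original row ids."""
        return cut_tree_labels(self.row_linkage, self.row_ids, k)


def cim_cluster(matrix: pd.DataFrame) -> CIMResult:
    """Clustered image map: complete-linkage agglomeration with Euclidean
    distance on both axes; leaf order is scipy's deterministic order
    (ties resolved by input index, so sort your ids for stability)."""
    if matrix.shape[0] < 2:
        raise ValueError("CIM needs at least two rows")
    rl = sch.linkage(matrix.to_numpy(), method="complete", metric="euclidean")
    ro = sch.leaves_list(rl).tolist()
    if matrix.shape[1] >= 2:
        cl = sch.linkage(matrix.to_numpy().T, method="complete",
                         metric="euclidean")
        co = sch.leaves_list(cl).tolist()
    else:
        cl = np.empty((0, 4))
        co = list(range(matrix.shape[1]))
    ordered = matrix.iloc[ro, co]
    return CIMResult(ordered, rl, cl, ro, co,
                     list(matrix.index), list(matrix.columns))


def cut_tree_labels(linkage: np.ndarray, ids, k: int) -> pd.Series:
    """Cut a dendrogram into k clusters; labels indexed by the original ids."""
    lab = sch.fcluster(linkage, k, criterion="maxclust")
    return pd.Series(lab, index=ids)


def linkage_to_newick(linkage: np.ndarray, leaf_names) -> str:
    """Serialize a scipy linkage matrix as a Newick string with branch
    lengths derived from merge heights."""
    tree = sch.to_tree(linkage)
    names = list(leaf_names)

    def rec(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"
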