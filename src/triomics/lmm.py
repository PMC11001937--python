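"""Per-feature differential abundance with family-correlated residuals.

Each feature is modeled as value = mu + generation fixed effect + family
random intercept + residual.  Variance components come from a REML fit;
the overall generation effect is tested by a likelihood-ratio test of
nested maximum-likelihood fits (chi-square, 2 df for three generations),
and pairwise generation contrasts (Infant-Mother, Infant-Grandmother,
Mother-Grandmother) by Wald tests on the REML estimates.  Multiplicity is
controlled per contrast across features by Benjamini-Hochberg.

Subjects without a recorded family become singleton groups, which leaves
their residuals independent, as they should be.

The solver profiles the likelihood over the variance ratio
theta = var_family / var_residual: for a single random intercept the
marginal covariance is block diagonal with blocks I + theta * J, whose
inverse and determinant are closed-form, so (RE)ML reduces to a 1-D
optimization.  This makes per-feature fits exact and fast; agreement
with a general-purpose mixed-model implementation is enforced in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize as opt
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .synth import GENERATIONS

CONTRASTS = (
    ("Infant", "Mother"),
    ("Infant", "Grandmother"),
    ("Mother", "Grandmother"),
)


@dataclass
class LMMResult:
    feature: str
    estimates: dict  # contrast name -> difference (first minus second group)
    se: dict
    p_contrast: dict
    p_overall: float
    var_family: float
    var_residual: float
    boundary: bool = False  # family variance pinned at zero
    flags: list = field(default_factory=list)


@dataclass
class _ProfiledFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float  # residual variance
    tau2: float  # random-intercept variance
    llf: float
    theta: float


def _profiled_lmm(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, reml: bool = True
) -> _ProfiledFit:
    """Exact (RE)ML for y = X b + Z u + e with one random intercept per
    group, by 1-D profile optimization over theta = tau^2 / sigma^2."""
    n, p = X.shape
    uniq, inv = np.unique(groups, return_inverse=True)
    sizes = np.bincount(inv).astype(float)
    # per-group sums of rows of X and of y
    SX = np.zeros((len(uniq), p))
    Sy = np.zeros(len(uniq))
    np.add.at(SX, inv, X)
    np.add.at(Sy, inv, y)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def pieces(theta: float):
        c = theta / (1.0 + sizes * theta)  # shrinkage per group
        XtWX = XtX - (SX * c[:, None]).T @ SX
        XtWy = Xty - SX.T @ (c * Sy)
        yWy = yty - float(c @ Sy**2)
        beta = np.linalg.solve(XtWX, XtWy)
        q = yWy - float(beta @ XtWy)  # GLS residual quadratic form
        logdetW = float(np.log1p(sizes * theta).sum())
        return beta, q, logdetW, XtWX

    def neg2ll(theta: float) -> float:
        _, q, logdetW, XtWX = pieces(theta)
        q = max(q, 1e-300)
        if reml:
            df = n - p
            s2 = q / df
            val = df * np.log(2 * np.pi * s2) + logdetW + df
            val += float(np.linalg.slogdet(XtWX)[1])
        else:
            s2 = q / n
            val = n * np.log(2 * np.pi * s2) + logdetW + n
        return val

    res = opt.minimize_scalar(
        lambda t: neg2ll(np.exp(t)),
        bounds=(np.log(1e-10), np.log(1e5)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    theta = float(np.exp(res.x))
    if neg2ll(0.0) <= res.fun:  # boundary: no family variance
        theta = 0.0
    beta, q, _, XtWX = pieces(theta)
    df = (n - p) if reml else n
    sigma2 = q / df
    return _ProfiledFit(
        beta=beta,
        cov_beta=sigma2 * np.linalg.inv(XtWX),
        sigma2=float(sigma2),
        tau2=float(theta * sigma2),
        llf=-0.5 * neg2ll(theta),
        theta=theta,
    )


def _design(generation: pd.Series) -> tuple[np.ndarray, list[str]]:
    present = [g for g in GENERATIONS if (generation == g).any()]
    X = np.ones((len(generation), len(present)))
    for j, g in enumerate(present[1:], start=1):
        X[:, j] = (generation == g).to_numpy(dtype=float)
    return X, present


def fit_lmm_feature(
    values,
    generation,
    family_id,
    feature: str = "feature",
) -> LMMResult:
    """REML mixed model for one feature; see module docstring for tests.

    Missing values are dropped pairwise.  Singular fits land on the
    boundary (family variance 0) and are flagged, never silently wrong.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "generation": np.asarray(generation),
            "family": np.asarray(family_id, dtype=object),
        }
    )
    df = df[df["y"].notna()].reset_index(drop=True)
    # unknown family -> singleton group
    blank = df["family"].isna() | (df["family"] == "")
    df.loc[blank, "family"] = [f"_solo{i}" for i in np.flatnonzero(blank)]
    gens = pd.unique(df["generation"])
    if len(gens) < 2:
        raise ValueError("need at least two generations present")
    if df["family"].nunique() < 2:
        raise ValueError("need at least two families")

    X, present = _design(df["generation"])
    groups = df["family"].to_numpy()
    flags: list[str] = []
    # standardize the response for optimizer stability; the model is
    # affine-equivariant so estimates are rescaled back afterwards
    y_raw = df["y"].to_numpy()
    y_loc, y_scale = y_raw.mean(), y_raw.std(ddof=1)
    if not np.isfinite(y_scale) or y_scale == 0:
        raise ValueError("constant response")
    ys = (y_raw - y_loc) / y_scale
    fit = _profiled_lmm(ys, X, groups, reml=True)
    boundary = fit.tau2 < 1e-8
    if boundary:
        flags.append("family variance at boundary (0)")
    # LRT of the generation term on ML fits
    fit_ml = _profiled_lmm(ys, X, groups, reml=False)
    fit0_ml = _profiled_lmm(ys, np.ones((len(df), 1)), groups, reml=False)
    lr = 2.0 * (fit_ml.llf - fit0_ml.llf)
    ddf = X.shape[1] - 1
    p_overall = float(st.chi2.sf(max(lr, 0.0), ddf)) if ddf > 0 else np.nan

    # Wald contrasts on the REML fit.  Column 0 is the reference-group
    # mean (first present generation); columns 1.. are offsets.
    beta = fit.beta
    cov = fit.cov_beta
    means = {}
    vecs = {}
    for j, g in enumerate(present):
        v = np.zeros(len(present))
        v[0] = 1.0
        if j > 0:
            v[j] = 1.0
        means[g] = float(v @ beta[: len(present)])
        vecs[g] = v
    estimates, se, p_contrast = {}, {}, {}
    for a, b in CONTRASTS:
        name = f"{a}-{b}"
        if a not in means or b not in means:
            continue
        v = vecs[a] - vecs[b]
        est = float(v @ beta[: len(present)])
        s = float(np.sqrt(v @ cov @ v))
        estimates[name] = est * y_scale
        se[name] = s * y_scale
        z = est / s if s > 0 else np.nan
        p_contrast[name] = float(2 * st.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return LMMResult(
        feature=feature,
        estimates=estimates,
        se=se,
        p_contrast=p_contrast,
        p_overall=p_overall,
        var_family=fit.tau2 * y_scale**2,
        var_residual=fit.sigma2 * y_scale**2,
        boundary=boundary,
        flags=flags,
    )


def fit_lmm_matrix(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit every feature; one row per feature per contrast with BH q
    computed per contrast across features, plus the overall test."""
    m = meta.set_index("sample_id").loc[matrix.index]
    rows = []
    for f in matrix.columns:
        try:
            res = fit_lmm_feature(matrix[f], m["generation"], m["family"], feature=f)
        except (ValueError, np.linalg.LinAlgError) as err:
            rows.append(
                {"feature": f, "contrast": "overall", "estimate": np.nan,
                 "se": np.nan, "p": np.nan, "var_family": np.nan,
                 "var_residual": np.nan, "flag": f"failed: {err}"}
            )
            continue
        base = {
            "feature": f,
            "var_family": res.var_family,
            "var_residual": res.var_residual,
            "flag": ";".join(res.flags),
        }
        rows.append({**base, "contrast": "overall", "estimate": np.nan,
                     "se": np.nan, "p": res.p_overall})
        for name in res.estimates:
            rows.append({**base, "contrast": name, "estimate": res.estimates[name],
                         "se": res.se[name], "p": res.p_contrast[name]})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for name, grp in out.groupby("contrast"):
        ok = grp["p"].notna()
        if ok.any():
            out.loc[grp.index[ok], "q"] = bh_fdr(grp.loc[ok, "p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, monotone in p."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def venn_partition(sets: dict) -> dict:
    """Region counts of the 3-set Venn diagram over significant-feature
    sets, keyed by sorted '&'-joined set names (e.g. 'A&B').  Counts of
    the 7 disjoint regions sum to the union size."""
    names = sorted(sets)
    if len(names) != 3:
        raise ValueError("venn_partition expects exactly three sets")
    a, b, c = (set(sets[n]) for n in names)
    regions = {
        names[0]: a - b - c,
        names[1]: b - a - c,
        names[2]: c - a - b,
        f"{names[0]}&{names[1]}": (a & b) - c,
        f"{names[0]}&{names[2]}": (a & c) - b,
        f"{names[1]}&{names[2]}": (b & c) - a,
        f"{names[0]}&{names[1]}&{names[2]}": a & b & c,
    }
    return {k: len(v) for k, v in regions.items()}


def lm_test_functional(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    max_sig: float = 0.10,
) -> pd.DataFrame:
    """Linear-model screen for functional (KO/pathway) abundances.

    Runs the same family-random-intercept engine on each column of a
    normalized functional table and flags features whose BH-adjusted
    overall generation p is at most ``max_sig``.  Constant columns are
    excluded with a flag.
    """
    const = table.columns[table.nunique() <= 1]
    res = fit_lmm_matrix(table.drop(columns=const), meta, alpha=max_sig)
    overall = res[res["contrast"] == "overall"].copy()
    overall["significant"] = overall["q"] <= max_sig
    for c in const:
        overall = pd.concat(
            [overall, pd.DataFrame([{"feature": c, "contrast": "overall",
                                     "p": np.nan, "q": np.nan,
                                     "significant": False,
                                     "flag": "constant feature"}])],
            ignore_index=True,
        )
    return overall.reset_index(drop=True)
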