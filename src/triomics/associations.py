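"""Taxa-metabolite association and pathway over-representation.

Spearman's rho is the Pearson correlation of mid-ranks (average ranks on
ties); its p-value uses the t approximation for n > 9 and the exact
permutation distribution for n <= 9, where the approximation is poor.
Over-representation uses the upper-tail hypergeometric probability
P(X >= k) with BH control across pathway sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
import scipy.stats as st

from .lmm import bh_fdr


@dataclass(frozen=True)
class PathwaySet:
    name: str
    members: frozenset
    universe: frozenset

    def __post_init__(self):
        if not self.members <= self.universe:
            raise ValueError(f"{self.name}: members must lie inside the universe")


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return np.nan
    return float((rx * ry).sum() / denom)


def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation and two-sided p.

    Ties get mid-ranks.  For n <= ``exact_max_n`` the p-value enumerates
    all n! orderings of one variable; otherwise the usual t approximation
    with n-2 degrees of freedom is used.  Constant input is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("spearman needs paired vectors with n >= 4")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("spearman undefined for a constant vector")
    rx = st.rankdata(x)
    ry = st.rankdata(y)
    rho = _rho_of_ranks(rx, ry)
    n = x.size
    if n <= exact_max_n:
        perms = np.array(list(permutations(ry)))
        rxc = rx - rx.mean()
        ryc = perms - ry.mean()
        denom = np.sqrt((rxc**2).sum() * (ryc[0] ** 2).sum())
        rhos = (ryc @ rxc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        t = rho * np.sqrt((n - 2) / max(1e-300, 1 - rho**2))
        p = float(2 * st.t.sf(abs(t), n - 2))
    return rho, p


def correlate_blocks(
    taxa_abund: pd.DataFrame,
    metabolite_matrix: pd.DataFrame,
    pairs,
) -> pd.DataFrame:
    """Spearman rho for each requested (taxon, metabolite) pair, with BH q
    across the table.  Sample sets must coincide."""
    extra = set(taxa_abund.index) ^ set(metabolite_matrix.index)
    if extra:
        raise ValueError(f"sample sets differ between blocks: {sorted(extra)[:5]}")
    met = metabolite_matrix.loc[taxa_abund.index]
    rows = []
    for taxon, metab in pairs:
        x = taxa_abund[taxon]
        y = met[metab]
        ok = x.notna() & y.notna()
        try:
            rho, p = spearman(x[ok], y[ok])
        except ValueError as err:
            rows.append({"taxon": taxon, "metabolite": metab, "rho": np.nan,
                         "p": np.nan, "flag": str(err)})
            continue
        rows.append({"taxon": taxon, "metabolite": metab, "rho": rho, "p": p,
                     "flag": ""})
    out = pd.DataFrame(rows, columns=["taxon", "metabolite", "rho", "p", "flag"])
    out["q"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "q"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    return out


def hypergeom_ora(hits, pathway: PathwaySet) -> float:
    """Upper-tail hypergeometric p: probability of >= k pathway members
    among |hits| draws from the universe."""
    hits = set(hits)
    if not hits <= pathway.universe:
        raise ValueError("hits must be a subset of the background universe")
    N = len(pathway.universe)
    K = len(pathway.members)
    n = len(hits)
    k = len(hits & pathway.members)
    return float(st.hypergeom.sf(k - 1, N, K, n))


def enrich_all(hits, pathway_sets) -> pd.DataFrame:
    """Per-pathway ORA with BH q, sorted by q then p then name."""
    rows = []
    for ps in pathway_sets:
        k = len(set(hits) & ps.members)
        rows.append(
            {"pathway": ps.name, "k": k, "K": len(ps.members),
             "n": len(set(hits)), "N": len(ps.universe),
             "p": hypergeom_ora(hits, ps)}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out = out.sort_values(["q", "p", "pathway"]).reset_index(drop=True)
    return out


def pathway_sets_from_annotations(
    annotations: pd.DataFrame,
    feature_col: str = "feature",
    pathway_col: str = "pathway",
) -> list[PathwaySet]:
    """Build pathway sets from a feature-annotation table; the background
    universe is all annotated, measured features."""
    anno = annotations[annotations[pathway_col].astype(str) != ""]
    universe = frozenset(anno[feature_col])
    return [
        PathwaySet(name, frozenset(grp[feature_col]), universe)
        for name, grp in anno.groupby(pathway_col)
    ]
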