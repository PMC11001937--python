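"""Functional-profile handling: TMM normalization of KO count libraries
and aggregation to BRITE level-B/C pathway tables.

TMM follows the canonical definition: per sample, the precision-weighted
trimmed mean of per-gene log2 ratios (M) against a reference library,
trimming 30% of the M distribution and 5% of the A (average-abundance)
distribution on each relevant side, with factors centered so their
geometric mean is 1.  The reference is the library whose upper-quartile
(of counts/library-size) is closest to the mean upper quartile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> float:
    """TMM factor of one library against the reference (log2 scale -> 2**)."""
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok], ref[ok]
    if obs.size == 0:
        return 1.0
    M = np.log2((obs / n_obs) / (ref / n_ref))
    A = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    if np.allclose(M, M[0]):
        return float(2 ** M[0])
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    n = M.size
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - (np.floor(n * logratio_trim) + 1)
    lo_a, hi_a = np.floor(n * sum_trim) + 1, n + 1 - (np.floor(n * sum_trim) + 1)
    rank_m = pd.Series(M).rank().to_numpy()
    rank_a = pd.Series(A).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = (w[keep] * M[keep]).sum() / w[keep].sum()
    return float(2**f)


def tmm_factors(counts: pd.DataFrame, ref: str | None = None) -> pd.Series:
    """Per-sample TMM normalization factors (geometric mean 1).

    ``counts`` is samples x features.  ``ref`` names the reference sample;
    by default the library whose 75th percentile of counts/library-size is
    closest to the mean such percentile.
    """
    if counts.shape[0] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=1).astype(float)
    if (lib <= 0).any():
        bad = counts.index[lib <= 0].tolist()
        raise ValueError(f"all-zero library: {bad}")
    X = counts.to_numpy(dtype=float)
    f75 = np.array([np.quantile(x / n, 0.75) for x, n in zip(X, lib)])
    if ref is None:
        ref_i = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_i = counts.index.get_loc(ref)
    factors = np.array(
        [
            _tmm_pair(X[i], X[ref_i], lib.iloc[i], lib.iloc[ref_i])
            if i != ref_i
            else 1.0
            for i in range(len(counts))
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.index, name="tmm_factor")


def tmm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts scaled to effective library size (lib x factor), as
    counts-per-million."""
    factors = tmm_factors(counts)
    eff = counts.sum(axis=1) * factors
    return counts.div(eff, axis=0) * 1e6


def aggregate_brite(
    ko_counts: pd.DataFrame, brite_map: pd.DataFrame, level: str
) -> pd.DataFrame:
    """Sum KO counts into BRITE hierarchies.

    ``brite_map`` has columns ``ko, level_b, level_c`` with one row per
    (KO, level-C) membership; KOs in several level-C entries contribute to
    each (the duplicated mass is visible in the aggregate total).  KOs
    absent from the map land in an "Unmapped" column.
    """
    col = {"B": "level_b", "C": "level_c"}.get(level)
    if col is None:
        raise ValueError("level must be 'B' or 'C'")
    mapping = brite_map[["ko", col]].drop_duplicates()
    out = {}
    mapped = set(mapping["ko"]) & set(ko_counts.columns)
    for name, grp in mapping.groupby(col):
        kos = [k for k in grp["ko"] if k in ko_counts.columns]
        if kos:
            out[name] = ko_counts[kos].sum(axis=1)
    unmapped = [k for k in ko_counts.columns if k not in mapped]
    if unmapped:
        out["Unmapped"] = ko_counts[unmapped].sum(axis=1)
    return pd.DataFrame(out, index=ko_counts.index)
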