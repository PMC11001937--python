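"""Community ecology on ASV count tables.

Relative abundance, aggregation to a taxonomic rank, minor-taxon lumping
(Fig-style "Minor phyla/genera" when below a cut in every group),
richness (observed taxa), and Shannon diversity with natural logarithm.
No rarefaction is applied; richness is computed on raw counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize to proportions; samples with zero total are dropped
    (flagged by omission)."""
    totals = counts.sum(axis=1)
    empty = totals == 0
    out = counts.loc[~empty].div(totals[~empty], axis=0)
    return out


def aggregate_rank(
    counts: pd.DataFrame, lineage: pd.DataFrame, rank: str
) -> pd.DataFrame:
    """Sum counts over taxa sharing a rank label; taxa without an
    assignment at that rank go to "Other"."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    lab = lineage.set_index("taxon")[rank].reindex(counts.columns)
    lab = lab.fillna("Other").replace("", "Other")
    return counts.T.groupby(lab.to_numpy()).sum().T


def lump_minor(
    proportions: pd.DataFrame,
    groups: pd.Series,
    cut: float,
    label: str = "Minor",
) -> pd.DataFrame:
    """Lump taxa whose mean relative abundance is below ``cut`` in every
    group into one ``label`` column.  Group means are means of per-sample
    proportions.  Conventional cuts: 0.001 for phyla, 0.02 for genera.
    """
    groups = pd.Series(np.asarray(groups), index=proportions.index)
    gm = proportions.groupby(groups.to_numpy()).mean()
    minor = (gm < cut).all(axis=0)
    if not minor.any():
        return proportions.copy()
    kept = proportions.loc[:, ~minor].copy()
    kept[label] = proportions.loc[:, minor].sum(axis=1)
    return kept


def richness(sample_counts) -> int:
    """Number of taxa observed (count > 0) in a sample."""
    v = np.asarray(sample_counts, dtype=float)
    return int((v > 0).sum())


def shannon(sample_counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i over observed taxa."""
    v = np.asarray(sample_counts, dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an empty sample")
    p = v[v > 0] / total
    return float(-(p * np.log(p)).sum())


def alpha_diversity(counts: pd.DataFrame) -> pd.DataFrame:
    """Richness and Shannon per sample."""
    return pd.DataFrame(
        {
            "richness": [richness(r) for _, r in counts.iterrows()],
            "shannon": [shannon(r) if r.sum() > 0 else np.nan
                        for _, r in counts.iterrows()],
        },
        index=counts.index,
    )
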