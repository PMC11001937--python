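"""Headline metabolite-class ratios.

SCFA/BCFA: (acetic + propionic + valeric + caproic) over the seven
branched-chain fatty acids.  MUFA/PUFA: the single co-eluting
"Linoleic Acid/Oleic Acid" feature over (arachidonic + eicosatrienoic +
docosahexaenoic).  Both operate on relative abundances, so they are
invariant to any global positive rescaling of the matrix.

Metabolite names are matched exactly after alias resolution; pass an
``aliases`` mapping when your annotation strings differ from the
canonical names shipped here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import BCFA_DENOMINATOR, MUFA_NUMERATOR, PUFA_DENOMINATOR, SCFA_NUMERATOR


@dataclass(frozen=True)
class RatioDefinition:
    name: str
    numerator: tuple
    denominator: tuple

    def __post_init__(self):
        if not self.numerator or not self.denominator:
            raise ValueError("numerator and denominator lists must be non-empty")
        if set(self.numerator) & set(self.denominator):
            raise ValueError("numerator and denominator must be disjoint")


SCFA_BCFA = RatioDefinition("SCFA/BCFA", SCFA_NUMERATOR, BCFA_DENOMINATOR)
MUFA_PUFA = RatioDefinition("MUFA/PUFA", MUFA_NUMERATOR, PUFA_DENOMINATOR)


def compute_ratio(
    matrix: pd.DataFrame,
    definition: RatioDefinition,
    aliases: dict | None = None,
) -> pd.Series:
    """Per-sample sum(numerator) / sum(denominator).

    Raises KeyError naming any metabolite absent from the matrix; returns
    NaN (flagged via the result's name attribute semantics) where the
    denominator sums to zero.
    """
    aliases = aliases or {}
    col = {aliases.get(c, c): c for c in matrix.columns}
    missing = [m for m in definition.numerator + definition.denominator if m not in col]
    if missing:
        raise KeyError(f"{definition.name}: metabolite(s) not in matrix: {missing}")
    num = matrix[[col[m] for m in definition.numerator]].sum(axis=1, skipna=True)
    den = matrix[[col[m] for m in definition.denominator]].sum(axis=1, skipna=True)
    out = num / den.where(den > 0, np.nan)
    out.name = definition.name
    return out


def scfa_bcfa_ratio(matrix: pd.DataFrame, aliases: dict | None = None) -> pd.Series:
    return compute_ratio(matrix, SCFA_BCFA, aliases)


def mufa_pufa_ratio(matrix: pd.DataFrame, aliases: dict | None = None) -> pd.Series:
    return compute_ratio(matrix, MUFA_PUFA, aliases)
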