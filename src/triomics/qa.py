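"""Quality assurance for raw GC-MS feature matrices.

The QA pipeline runs blank subtraction, then a presence filter, then a
QC-RSD filter — the conventional gate order for pooled-QC untargeted
metabolomics.  Equilibrium QCs (the conditioning injections that open a
batch) are excluded from every QC statistic.  A :class:`QAReport`
reconciles feature counts across stages and records one reason code per
removed feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class QAError(ValueError):
    pass


@dataclass
class QAReport:
    """Per-stage bookkeeping for a QA run."""

    stage_counts: dict[str, int] = field(default_factory=dict)
    removed: dict[str, str] = field(default_factory=dict)  # feature -> reason code
    qc_rsd: pd.DataFrame | None = None  # features x batches
    tus: pd.Series | None = None
    is_rsd: pd.DataFrame | None = None
    flags: list[str] = field(default_factory=list)

    def record(self, stage: str, kept, dropped, reason: str) -> None:
        self.stage_counts[stage] = len(kept)
        for f in dropped:
            self.removed.setdefault(f, reason)

    def validate(self) -> None:
        counts = list(self.stage_counts.values())
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise QAError("stage feature counts must be non-increasing")


def _roles(meta: pd.DataFrame, matrix: pd.DataFrame) -> pd.DataFrame:
    m = meta.set_index("sample_id").loc[matrix.index]
    return m


def interspersed_qc_mask(meta: pd.DataFrame, matrix: pd.DataFrame) -> np.ndarray:
    """QC injections usable for statistics (equilibrium QCs excluded)."""
    m = _roles(meta, matrix)
    mask = (m["role"] == "qc").to_numpy()
    if "qc_kind" in m.columns:
        mask &= (m["qc_kind"] != "equilibrium").to_numpy()
    return mask


def subtract_blanks(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    blank_ratio: float = 3.0,
    report: QAReport | None = None,
) -> pd.DataFrame:
    """Remove features not sufficiently above the blank background.

    A feature is dropped when its mean study-sample signal is below
    ``blank_ratio`` times its mean blank signal; remaining features are
    returned unchanged.  Raises :class:`QAError` when the matrix carries
    no blank injections (skip the stage explicitly in that case).
    """
    m = _roles(meta, matrix)
    blanks = (m["role"] == "blank").to_numpy()
    study = (m["role"] == "study").to_numpy()
    if blanks.sum() == 0:
        raise QAError(
            "no blank injections present; call the QA pipeline with "
            "blank_subtraction disabled to skip this stage explicitly"
        )
    blank_mean = matrix.iloc[blanks].mean(skipna=True).fillna(0.0)
    study_mean = matrix.iloc[study].mean(skipna=True).fillna(0.0)
    keep = study_mean >= blank_ratio * blank_mean
    out = matrix.loc[:, keep[keep].index]
    if report is not None:
        report.record("blank_subtraction", out.columns,
                      [f for f in matrix.columns if not keep[f]], "blank")
        if out.shape[1] == 0:
            report.flags.append("all features removed by blank subtraction")
    if out.shape[1] == 0:
        warnings.warn("blank subtraction removed every feature", stacklevel=2)
    return out


def presence_filter(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    qc_min: float = 0.50,
    sample_min: float = 0.70,
    connective: str = "and",
    report: QAReport | None = None,
) -> pd.DataFrame:
    """Presence (detection-frequency) filter, applied per batch.

    "Present" means non-missing and > 0.  Within a batch a feature passes
    when it is present in >= ``qc_min`` of interspersed QCs AND
    >= ``sample_min`` of study samples (``connective="and"``, the
    default strict reading) or in either fraction (``connective="or"``).
    A feature is kept if it passes in at least one batch, mirroring
    batch-wise QA.
    """
    if connective not in ("and", "or"):
        raise ValueError("connective must be 'and' or 'or'")
    m = _roles(meta, matrix)
    qc_mask = interspersed_qc_mask(meta, matrix)
    if qc_mask.sum() == 0:
        raise QAError("presence filter requires interspersed QC injections")
    present = matrix.notna() & (matrix > 0)
    keep = pd.Series(False, index=matrix.columns)
    for batch in sorted(m["batch"].unique()):
        in_batch = (m["batch"] == batch).to_numpy()
        qcs = present.iloc[in_batch & qc_mask]
        studies = present.iloc[in_batch & (m["role"] == "study").to_numpy()]
        if len(qcs) == 0:
            continue
        qc_ok = qcs.mean() >= qc_min
        s_ok = studies.mean() >= sample_min
        ok = (qc_ok & s_ok) if connective == "and" else (qc_ok | s_ok)
        keep |= ok
    out = matrix.loc[:, keep[keep].index]
    if report is not None:
        report.record("presence_filter", out.columns,
                      [f for f in matrix.columns if not keep[f]], "presence")
    return out


def compute_rsd(values) -> float:
    """Relative standard deviation, percent: 100 * sd / mean.

    Uses the sample (ddof=1) standard deviation.  Undefined for fewer
    than two non-missing values or a non-positive mean.
    """
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    if v.size < 2:
        raise QAError("RSD needs at least 2 non-missing values")
    mean = v.mean()
    if mean <= 0:
        raise QAError("RSD undefined for non-positive mean")
    return float(100.0 * v.std(ddof=1) / mean)


def qc_rsd_table(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-feature QC RSD per batch (interspersed QCs only); NaN where
    undefined."""
    m = _roles(meta, matrix)
    qc_mask = interspersed_qc_mask(meta, matrix)
    out = {}
    for batch in sorted(m["batch"].unique()):
        sel = matrix.iloc[qc_mask & (m["batch"] == batch).to_numpy()]
        col = []
        for f in matrix.columns:
            try:
                col.append(compute_rsd(sel[f]))
            except QAError:
                col.append(np.nan)
        out[batch] = col
    return pd.DataFrame(out, index=matrix.columns)


def rsd_filter(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    threshold: float = 30.0,
    mode: str = "any",
    report: QAReport | None = None,
) -> pd.DataFrame:
    """QC-reproducibility filter.

    ``mode="any"`` keeps a feature whose QC RSD is below ``threshold`` in
    at least one batch (the study's rule); ``mode="all"`` requires every
    batch — the stricter criterion whose pass count is the sensitive
    indicator of normalization quality.
    """
    if mode not in ("any", "all"):
        raise ValueError("mode must be 'any' or 'all'")
    rsd = qc_rsd_table(matrix, meta)
    below = rsd < threshold
    keep = below.any(axis=1) if mode == "any" else below.all(axis=1)
    out = matrix.loc[:, keep[keep].index]
    if report is not None:
        report.qc_rsd = rsd
        report.record(f"rsd_filter_{mode}", out.columns,
                      [f for f in matrix.columns if not keep[f]], "rsd")
    return out


def compute_tus(matrix: pd.DataFrame, report: QAReport | None = None) -> pd.Series:
    """Total useful signal: per-sample sum of non-missing intensities."""
    if matrix.shape[1] == 0:
        raise QAError("TUS undefined on an empty matrix")
    tus = matrix.sum(axis=1, skipna=True)
    all_missing = matrix.isna().all(axis=1)
    if report is not None:
        report.tus = tus
        for sid in matrix.index[all_missing]:
            report.flags.append(f"sample {sid}: all features missing, TUS=0")
    return tus


def is_diagnostics(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    is_feature_ids,
    report: QAReport | None = None,
) -> pd.DataFrame:
    """Per-batch RSD of each internal standard across all injections."""
    missing = [f for f in is_feature_ids if f not in matrix.columns]
    if missing:
        raise QAError(f"internal standard feature(s) not in matrix: {missing}")
    m = _roles(meta, matrix)
    rows = {}
    for f in is_feature_ids:
        rows[f] = {
            batch: compute_rsd(matrix.loc[(m["batch"] == batch).to_numpy(), f])
            for batch in sorted(m["batch"].unique())
        }
    table = pd.DataFrame(rows).T
    if report is not None:
        report.is_rsd = table
    return table


def run_qa(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    blank_ratio: float = 3.0,
    qc_min: float = 0.50,
    sample_min: float = 0.70,
    rsd_threshold: float = 30.0,
    connective: str = "and",
    blank_subtraction: bool = True,
) -> tuple[pd.DataFrame, QAReport]:
    """Full QA pipeline: blanks -> presence -> RSD ("any batch" mode).

    Returns the filtered matrix (blank/QC rows retained for the
    normalization stage) and a reconciled :class:`QAReport` that also
    carries the "all batches" RSD pass count for reference.
    """
    report = QAReport()
    report.stage_counts["input"] = matrix.shape[1]
    out = matrix
    if blank_subtraction:
        out = subtract_blanks(out, meta, blank_ratio, report)
    out = presence_filter(out, meta, qc_min, sample_min, connective, report)
    out = rsd_filter(out, meta, rsd_threshold, "any", report)
    strict = rsd_filter(out, meta, rsd_threshold, "all")
    report.stage_counts["rsd_all_batches_reference"] = strict.shape[1]
    compute_tus(out, report)
    report.validate()
    return out, report
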