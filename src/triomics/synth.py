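"""Synthetic three-generation cohort generator.

Emulates the data structure of a large-scale fecal multi-omics study:
three GC-MS batches (one age group per batch: Mothers, Grandmothers,
Infants) with pooled-QC injections and blanks, multiplicative
injection-order drift and batch-level offsets, generation effects with
family-correlated residuals on the log scale, left-censored missingness,
blank background on a contaminant feature subset, infant-vs-adult
compositional shifts in a 16S-style taxa table, and KO (gene-family)
counts drawn as taxa-abundance-weighted mixtures of genome profiles.

Every generator takes an explicit :class:`numpy.random.Generator` or a
seed and is byte-deterministic under a fixed seed.  Ground truth (drift
curves, batch factors, true effect sizes, informative flags) is recorded
so recovery can be tested.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENERATIONS = ("Infant", "Mother", "Grandmother")
#: one generation per batch, mirroring the study worklist
BATCH_OF_GENERATION = {"Mother": 1, "Grandmother": 2, "Infant": 3}

# internal standards: IS1 controls derivatization, IS2 instrument response
IS_FEATURES = ("4-Methylvaleric acid (IS1)", "Tricosane (IS2)")

SCFA_NUMERATOR = ("Acetic acid", "Propionic acid", "Valeric acid", "Caproic acid")
BCFA_DENOMINATOR = (
    "Isotridecanoic acid",
    "Isomyristic acid",
    "Isopentadecanoic acid",
    "Anteisopentadecanoic acid",
    "Iso/Anteisopalmitic acid",
    "Isomargaric acid",
    "Anteisomargaric acid",
)
MUFA_NUMERATOR = ("Linoleic Acid/Oleic Acid",)
PUFA_DENOMINATOR = ("Arachidonic acid", "Eicosatrienoic acid", "Docosahexaenoic acid")

NAMED_FEATURES = (
    SCFA_NUMERATOR + BCFA_DENOMINATOR + MUFA_NUMERATOR + PUFA_DENOMINATOR + IS_FEATURES
)


# --------------------------------------------------------------------------- cohort


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout: subjects per generation and family linkage.

    Defaults mirror the study batches (67 Mothers, 63 Grandmothers,
    67 Infants analysed as one single-generation batch each).
    ``n_per_generation`` is ordered (Infant, Mother, Grandmother).
    ``missing_family_rate`` is the fraction of subjects whose family
    link is unrecorded (they become singleton families downstream).
    """

    n_per_generation: tuple[int, int, int] = (67, 67, 63)
    n_families: int = 67
    missing_family_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_generation):
            raise ValueError("n_per_generation entries must be >= 1")
        if self.n_families < max(self.n_per_generation):
            raise ValueError(
                f"n_families={self.n_families} is smaller than the largest "
                f"generation count {max(self.n_per_generation)}"
            )
        if not 0.0 <= self.missing_family_rate < 1.0:
            raise ValueError("missing_family_rate must be in [0, 1)")


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate study-sample metadata: one row per subject.

    Each family holds at most one Infant, one Mother and one Grandmother;
    generations with fewer subjects than families leave some families
    incomplete (chosen at random).  Columns: ``sample_id, subject_id,
    family, generation, batch``.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for gen, n in zip(GENERATIONS, config.n_per_generation):
        fams = np.sort(rng.choice(config.n_families, size=n, replace=False))
        for i, fam in enumerate(fams):
            sid = f"{gen[0]}{i + 1:03d}"
            rows.append(
                {
                    "sample_id": sid,
                    "subject_id": sid,
                    "family": f"F{fam + 1:03d}",
                    "generation": gen,
                    "batch": BATCH_OF_GENERATION[gen],
                }
            )
    meta = pd.DataFrame(rows)
    if config.missing_family_rate > 0:
        drop = rng.random(len(meta)) < config.missing_family_rate
        meta.loc[drop, "family"] = pd.NA
    return meta


# --------------------------------------------------------------------------- worklist


@dataclass
class WorklistLayout:
    """Ordered injections for all batches.

    ``table`` has one row per injection: ``sample_id, batch,
    injection_order, role`` (study/qc/blank) and ``qc_kind``
    (equilibrium/interspersed or empty).  Per batch: 3 equilibrium QCs
    open the run, 8 interspersed QCs are placed every 9-10 injections,
    and blanks sit after equilibration and at the end of the run.
    """

    table: pd.DataFrame
    n_equilibrium: int = 3
    n_interspersed: int = 8

    def validate(self) -> None:
        for batch, sub in self.table.groupby("batch"):
            orders = np.sort(sub["injection_order"].to_numpy())
            if not np.array_equal(orders, np.arange(1, len(sub) + 1)):
                raise ValueError(f"batch {batch}: injection orders not contiguous")
            n_qc = (sub["role"] == "qc").sum()
            if n_qc != self.n_equilibrium + self.n_interspersed:
                raise ValueError(f"batch {batch}: expected 11 QCs, found {n_qc}")


def build_worklist(
    meta: pd.DataFrame,
    seed: int = 0,
    n_equilibrium: int = 3,
    n_interspersed: int = 8,
    n_blanks: int = 2,
) -> WorklistLayout:
    """Lay out each batch: equilibrium QCs, randomized study samples with
    interspersed QCs splitting the run into near-equal stretches, blanks
    after equilibration and at the end."""
    rng = np.random.default_rng(seed)
    rows = []
    for batch in sorted(meta["batch"].unique()):
        sids = meta.loc[meta["batch"] == batch, "sample_id"].to_numpy()
        sids = rng.permutation(sids)
        chunks = np.array_split(sids, n_interspersed)
        order = 0
        qc_i = 0

        def push(sample_id, role, qc_kind=""):
            nonlocal order
            order += 1
            rows.append(
                {
                    "sample_id": sample_id,
                    "batch": batch,
                    "injection_order": order,
                    "role": role,
                    "qc_kind": qc_kind,
                    "generation": "",
                    "family": "",
                }
            )

        for i in range(n_equilibrium):
            push(f"B{batch}_QCEQ{i + 1}", "qc", "equilibrium")
        if n_blanks > 0:
            push(f"B{batch}_BLANK1", "blank")
        for chunk in chunks:
            for sid in chunk:
                push(sid, "study")
            qc_i += 1
            push(f"B{batch}_QC{qc_i:02d}", "qc", "interspersed")
        for b in range(1, n_blanks):
            push(f"B{batch}_BLANK{b + 1}", "blank")

    table = pd.DataFrame(rows)
    # carry study annotations onto the injection table
    anno = meta.set_index("sample_id")
    mask = table["role"] == "study"
    table.loc[mask, "generation"] = anno.loc[
        table.loc[mask, "sample_id"], "generation"
    ].to_numpy()
    table.loc[mask, "family"] = anno.loc[table.loc[mask, "sample_id"], "family"].to_numpy()
    layout = WorklistLayout(table, n_equilibrium, n_interspersed)
    layout.validate()
    return layout


# --------------------------------------------------------------------------- metabolome truth


@dataclass
class DriftTruth:
    """Ground truth for the metabolome generator.

    Drift is multiplicative in injection order, per feature x batch:
    ``d(o) = 1 + slope * x + amp * sin(2*pi*x + phase)`` with
    ``x = o / n_injections`` — a random mixture of a linear and a smooth
    periodic component, constrained strictly positive.  Batch offsets are
    per-feature log-normal factors.  Generation effects are additive on
    the log scale and exactly zero for null features.
    """

    features: list[str]
    batches: list[int]
    drift_slope: np.ndarray  # (F, B)
    drift_amp: np.ndarray  # (F, B)
    drift_phase: np.ndarray  # (F, B)
    batch_factor: np.ndarray  # (F, B)
    base_log: np.ndarray  # (F,)
    gen_effects: np.ndarray  # (F, 3) log-scale, order GENERATIONS
    family_sd: np.ndarray  # (F,)
    residual_sd: np.ndarray  # (F,)
    missing_rate: np.ndarray  # (F,)
    blank_background: np.ndarray  # (F,)
    informative: np.ndarray  # (F,) bool
    contaminant: np.ndarray  # (F,) bool
    qc_noise_cv: float = 0.02
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        lo = 1.0 - np.abs(self.drift_slope) - np.abs(self.drift_amp)
        if np.any(lo <= 0):
            raise ValueError("drift curve not strictly positive")
        null = ~self.informative
        if np.any(self.gen_effects[null] != 0):
            raise ValueError("null features must carry zero generation effects")

    def drift_curve(self, feature_idx: int, batch_idx: int, orders: np.ndarray,
                    n_injections: int) -> np.ndarray:
        x = np.asarray(orders, dtype=float) / n_injections
        return (
            1.0
            + self.drift_slope[feature_idx, batch_idx] * x
            + self.drift_amp[feature_idx, batch_idx]
            * np.sin(2 * np.pi * x + self.drift_phase[feature_idx, batch_idx])
        )


_PATHWAYS = (
    "Butanoate metabolism",
    "Propanoate metabolism",
    "Fatty acid biosynthesis",
    "Tryptophan metabolism",
    "Arginine and proline metabolism",
    "Citrate cycle (TCA cycle)",
    "Glycolysis / Gluconeogenesis",
    "Valine, leucine and isoleucine degradation",
    "Phenylalanine metabolism",
    "Bile secretion",
    "Purine metabolism",
    "Galactose metabolism",
)

_CLASSES = (
    "Fatty acid",
    "Amino acid",
    "Organic acid",
    "Indole",
    "Polyamine",
    "Sugar",
    "Sterol",
)


def make_drift_truth(
    n_features: int = 150,
    n_batches: int = 3,
    drift_lo: float = 0.3,
    drift_hi: float = 0.8,
    informative_frac: float = 0.30,
    effect_lo: float = 0.5,
    effect_hi: float = 1.5,
    family_sd: float = 0.25,
    residual_sd: float = 0.5,
    missing_frac: float = 0.25,
    missing_rate_hi: float = 0.15,
    n_contaminants: int = 8,
    qc_noise_cv: float = 0.02,
    batch_log_sd: float = 0.3,
    seed: int = 0,
) -> DriftTruth:
    """Draw a ground-truth parameter set.

    ``drift_lo``/``drift_hi`` bound the linear drift amplitude across a
    batch (0.3-0.8 means the drift factor moves by 30-80% over the run).
    ``informative_frac`` of generic features carry non-zero generation
    effects of log-magnitude ``effect_lo``-``effect_hi``; effects are
    concentrated in three "driven" pathways so downstream enrichment has
    a planted signal.  The named ratio metabolites and two internal
    standards are always included and given study-motivated effect
    patterns (acetic acid up in Infants, longer SCFAs/BCFAs and the
    MUFA feature up with age; internal standards effect-free).
    """
    rng = np.random.default_rng(seed)
    named = list(NAMED_FEATURES)
    n_generic = max(0, n_features - len(named))
    features = named + [f"M{i + 1:04d}" for i in range(n_generic)]
    F = len(features)
    idx = {f: i for i, f in enumerate(features)}

    sign = rng.choice([-1.0, 1.0], size=(F, n_batches))
    drift_slope = sign * rng.uniform(drift_lo, drift_hi, size=(F, n_batches))
    drift_amp = rng.uniform(0.0, np.maximum(0.0, 0.95 - np.abs(drift_slope)) * 0.2)
    drift_phase = rng.uniform(0, 2 * np.pi, size=(F, n_batches))
    batch_factor = np.exp(rng.normal(0.0, batch_log_sd, size=(F, n_batches)))

    base_log = rng.normal(np.log(1e5), 0.8, size=F)
    gen_effects = np.zeros((F, 3))
    informative = np.zeros(F, dtype=bool)

    # pathway assignment for generic features; three pathways carry the
    # planted block of effects
    pathway = np.array([""] * F, dtype=object)
    mclass = np.array([""] * F, dtype=object)
    for f in features[: len(named)]:
        pathway[idx[f]] = (
            "Butanoate metabolism"
            if f in SCFA_NUMERATOR + BCFA_DENOMINATOR
            else "Fatty acid biosynthesis"
        )
        mclass[idx[f]] = "Fatty acid"
    gen_idx = np.arange(len(named), F)
    pathway[gen_idx] = rng.choice(_PATHWAYS, size=len(gen_idx))
    mclass[gen_idx] = rng.choice(_CLASSES, size=len(gen_idx))

    driven = set(rng.choice(_PATHWAYS, size=3, replace=False))
    for i in gen_idx:
        p_inf = 0.85 if pathway[i] in driven else informative_frac * 0.5
        if rng.random() < p_inf:
            informative[i] = True
            mag = rng.uniform(effect_lo, effect_hi) * rng.choice([-1.0, 1.0])
            pattern = rng.choice(["age", "infant"])
            if pattern == "age":  # monotone with age
                gen_effects[i] = (0.0, 0.65 * mag, mag)
            else:  # infant-specific shift
                gen_effects[i] = (mag, 0.0, 0.0)

    def set_effect(name: str, eff: tuple[float, float, float], base_shift: float = 0.0):
        i = idx[name]
        informative[i] = True
        gen_effects[i] = eff
        base_log[i] += base_shift

    # study-motivated patterns: acetic up in Infants and high-abundance;
    # longer SCFAs, BCFAs and the MUFA feature increase with age
    set_effect("Acetic acid", (1.2, 0.0, 0.0), base_shift=2.0)
    for name in ("Propionic acid", "Valeric acid", "Caproic acid"):
        set_effect(name, (0.0, 0.5, 0.7))
    for name in BCFA_DENOMINATOR:
        set_effect(name, (0.0, 0.8, 1.1))
    set_effect("Linoleic Acid/Oleic Acid", (0.0, 0.6, 0.9), base_shift=1.0)
    for name in PUFA_DENOMINATOR:
        set_effect(name, (0.3, 0.0, 0.0))
    for name in IS_FEATURES:  # spiked standards: no biology, tight noise
        i = idx[name]
        informative[i] = False
        gen_effects[i] = 0.0
        base_log[i] = np.log(5e5)

    family_sd_arr = np.full(F, family_sd)
    residual_sd_arr = np.full(F, residual_sd)
    is_idx = [idx[n] for n in IS_FEATURES]
    family_sd_arr[is_idx] = 0.0
    residual_sd_arr[is_idx] = 0.02

    missing_rate = np.zeros(F)
    cand = rng.permutation(gen_idx)[: int(missing_frac * len(gen_idx))]
    missing_rate[cand] = rng.uniform(0.02, missing_rate_hi, size=len(cand))

    blank_background = np.zeros(F)
    contaminant = np.zeros(F, dtype=bool)
    cont = rng.permutation(gen_idx)[:n_contaminants]
    contaminant[cont] = True
    # contaminants are reagent/solvent signals: the blank carries the
    # bulk of the intensity and study samples add little on top
    blank_background[cont] = np.exp(base_log[cont]) * rng.uniform(0.8, 1.5, len(cont))
    base_log[cont] += np.log(0.3)
    informative[cont] = False
    gen_effects[cont] = 0.0

    annotations = pd.DataFrame(
        {
            "feature": features,
            "metabolite_class": mclass,
            "pathway": pathway,
            "platform": "GC-QTOF-MS",
            "is_internal_standard": [f in IS_FEATURES for f in features],
            "is_contaminant": contaminant,
            "informative": informative,
        }
    )
    return DriftTruth(
        features=features,
        batches=list(range(1, n_batches + 1)),
        drift_slope=drift_slope,
        drift_amp=drift_amp,
        drift_phase=drift_phase,
        batch_factor=batch_factor,
        base_log=base_log,
        gen_effects=gen_effects,
        family_sd=family_sd_arr,
        residual_sd=residual_sd_arr,
        missing_rate=missing_rate,
        blank_background=blank_background,
        informative=informative,
        contaminant=contaminant,
        qc_noise_cv=qc_noise_cv,
        annotations=annotations,
    )


def generate_metabolome(
    truth: DriftTruth,
    layout: WorklistLayout,
    meta: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate the raw (drifted, batch-offset) intensity matrix.

    Rows are injections (index = sample_id, worklist order), columns are
    features.  QC rows carry the pooled mean of the three generation base
    levels times drift, batch factor and analytical noise; study rows
    additionally carry their generation effect, family intercept and
    biological residual; blanks carry only the background signal.
    Missingness is applied by left-censoring each feature below its
    truth-specified detection quantile, plus a small random dropout.
    """
    table = layout.table
    study_ids = set(meta["sample_id"])
    lay_ids = set(table.loc[table["role"] == "study", "sample_id"])
    if study_ids != lay_ids:
        raise ValueError("worklist layout and metadata describe different study samples")

    rng = np.random.default_rng(seed)
    F = len(truth.features)
    batches = truth.batches
    bidx = {b: i for i, b in enumerate(batches)}
    gidx = {g: i for i, g in enumerate(GENERATIONS)}

    # pooled QC level: arithmetic mean of the generation base levels
    qc_level = np.exp(truth.base_log[:, None] + truth.gen_effects).mean(axis=1)

    # family random intercepts, one per (family, feature)
    fams = meta["family"].dropna().unique()
    fam_intercepts = {
        fam: rng.normal(0.0, truth.family_sd) for fam in sorted(fams)
    }

    n_per_batch = table.groupby("batch")["injection_order"].max().to_dict()
    X = np.zeros((len(table), F))
    for r, row in enumerate(table.itertuples(index=False)):
        b = bidx[row.batch]
        drift = truth.drift_curve(
            np.arange(F), b, np.full(F, row.injection_order), n_per_batch[row.batch]
        )
        noise = np.exp(rng.normal(0.0, truth.qc_noise_cv, size=F))
        if row.role == "blank":
            X[r] = truth.blank_background * noise
        elif row.role == "qc":
            X[r] = qc_level * drift * truth.batch_factor[:, b] * noise
        else:
            g = gidx[row.generation]
            u = (
                fam_intercepts[row.family]
                if isinstance(row.family, str) and row.family
                else rng.normal(0.0, truth.family_sd)
            )
            e = rng.normal(0.0, truth.residual_sd)
            level = np.exp(truth.base_log + truth.gen_effects[:, g] + u + e)
            bg = np.where(truth.contaminant, truth.blank_background, 0.0)
            X[r] = level * drift * truth.batch_factor[:, b] * noise + bg

    mat = pd.DataFrame(X, index=table["sample_id"].to_numpy(), columns=truth.features)
    mat.index.name = "sample_id"

    # left-censoring on study samples only: below the per-feature detection
    # quantile the value is not reported
    study_mask = (table["role"] == "study").to_numpy()
    for j in range(F):
        if truth.missing_rate[j] <= 0:
            continue
        vals = mat.iloc[study_mask, j]
        limit = np.quantile(vals, truth.missing_rate[j])
        mat.iloc[study_mask, j] = vals.where(vals >= limit, np.nan)
    dropout = (rng.random(mat.shape) < 0.005) & study_mask[:, None]
    is_cols = [truth.features.index(n) for n in IS_FEATURES if n in truth.features]
    dropout[:, is_cols] = False
    mat = mat.mask(dropout)
    return mat


# --------------------------------------------------------------------------- taxa

_PHYLA = {
    "Actinobacteria": ("Bifidobacterium", "Collinsella", "Eggerthella"),
    "Proteobacteria": ("Escherichia/Shigella", "Klebsiella", "Sutterella"),
    "Firmicutes": (
        "Veillonella",
        "Faecalibacterium",
        "Blautia",
        "Roseburia",
        "Ruminococcus",
        "Streptococcus",
        "Clostridium",
        "Lactobacillus",
        "Dorea",
        "Coprococcus",
    ),
    "Bacteroidetes": ("Bacteroides", "Prevotella", "Parabacteroides", "Alistipes"),
    "Verrucomicrobia": ("Akkermansia",),
    "Fusobacteria": ("Fusobacterium",),
}

INFANT_TOP3 = ("Bifidobacterium", "Escherichia/Shigella", "Veillonella")


@dataclass(frozen=True)
class TaxaConfig:
    """Community generator settings.

    ``concentration`` is the Dirichlet precision: sample compositions are
    Dirichlet(concentration x base proportions); larger means less
    overdispersion.  Infant base composition concentrates >50% of mass on
    Bifidobacterium, Escherichia/Shigella and Veillonella; adult
    compositions are flatter (higher expected Shannon diversity).
    """

    n_taxa: int = 200
    concentration: float = 50.0
    library_size: int = 20000
    infant_top3_share: float = 0.60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.library_size <= 0:
            raise ValueError("library sizes must be > 0")


def _taxa_frame(n_taxa: int, rng: np.random.Generator) -> pd.DataFrame:
    genera, phyla = [], []
    for ph, gs in _PHYLA.items():
        genera.extend(gs)
        phyla.extend([ph] * len(gs))
    asv_genus = np.concatenate(
        [np.array(genera), rng.choice(genera, size=max(0, n_taxa - len(genera)))]
    )[:n_taxa]
    g2p = dict(zip(genera, phyla))
    rows = []
    per_genus_count: dict[str, int] = {}
    for i, g in enumerate(asv_genus):
        per_genus_count[g] = per_genus_count.get(g, 0) + 1
        rows.append(
            {
                "taxon": f"ASV{i + 1:04d}",
                "domain": "Bacteria",
                "phylum": g2p[g],
                "class": f"{g2p[g]}_c",
                "order": f"{g2p[g]}_o",
                "family": f"{g}_f",
                "genus": g,
                "species": f"{g} sp{per_genus_count[g]}",
            }
        )
    return pd.DataFrame(rows)


def _base_proportions(
    lineage: pd.DataFrame, config: TaxaConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-generation expected composition over ASVs, rows sum to 1."""
    n = len(lineage)
    genus = lineage["genus"].to_numpy()
    # within-genus split, shared across generations
    split = rng.dirichlet(np.ones(n) * 2.0)
    props = np.zeros((3, n))
    for gi, gen in enumerate(GENERATIONS):
        if gen == "Infant":
            top_share = config.infant_top3_share
            gweights = {g: 0.0 for g in np.unique(genus)}
            top_parts = rng.dirichlet(np.array([5.0, 3.0, 2.0]))
            for g, part in zip(INFANT_TOP3, top_parts):
                gweights[g] = top_share * part
            rest = [g for g in gweights if g not in INFANT_TOP3]
            rest_parts = rng.dirichlet(np.ones(len(rest)) * 0.6)
            for g, part in zip(rest, rest_parts):
                gweights[g] = (1 - top_share) * part
        else:
            gweights = {}
            gs = list(np.unique(genus))
            parts = rng.dirichlet(np.ones(len(gs)) * 3.0)
            for g, part in zip(gs, parts):
                gweights[g] = part
        w = np.array([gweights[g] for g in genus]) * split
        # renormalize within genus so genus totals match gweights
        for g in np.unique(genus):
            m = genus == g
            s = w[m].sum()
            if s > 0:
                w[m] = w[m] / s * gweights[g]
        props[gi] = w / w.sum()
    return props


def generate_taxa(
    meta: pd.DataFrame, config: TaxaConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Dirichlet-multinomial ASV counts for study samples.

    Returns ``(counts, lineage, base_props)`` where counts is samples x
    taxa, lineage carries seven ranks per taxon, and ``base_props`` is
    the (3, n_taxa) ground-truth expected composition per generation.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lineage = _taxa_frame(config.n_taxa, rng)
    props = _base_proportions(lineage, config, rng)
    gidx = {g: i for i, g in enumerate(GENERATIONS)}
    counts = np.zeros((len(meta), config.n_taxa), dtype=int)
    for r, gen in enumerate(meta["generation"]):
        alpha = props[gidx[gen]] * config.concentration
        p = rng.dirichlet(np.maximum(alpha, 1e-8))
        counts[r] = rng.multinomial(config.library_size, p)
    table = pd.DataFrame(
        counts, index=meta["sample_id"].to_numpy(), columns=lineage["taxon"].to_numpy()
    )
    table.index.name = "sample_id"
    return table, lineage, props


# --------------------------------------------------------------------------- KO profiles

_BRITE_B = (
    "Carbohydrate metabolism",
    "Energy metabolism",
    "Lipid metabolism",
    "Nucleotide metabolism",
    "Amino acid metabolism",
    "Metabolism of cofactors and vitamins",
    "Glycan biosynthesis and metabolism",
    "Membrane transport",
    "Signal transduction",
    "Translation",
    "Replication and repair",
    "Cell motility",
)


@dataclass(frozen=True)
class KOConfig:
    n_kos: int = 500
    depth: int = 50000
    specific_frac: float = 0.4  # fraction of each genome's mass on its own KOs
    seed: int = 0


def make_genome_profiles(
    lineage: pd.DataFrame, config: KOConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-taxon KO composition (rows sum to 1) plus a BRITE map.

    Each genus shares a profile: a common core over all KOs plus a
    genus-specific block, so KO abundances are taxa-driven mixtures and
    taxa-KO correlation is built in.  Every KO maps to one BRITE level-B
    hierarchy and one or two level-C entries.
    """
    kos = [f"K{i + 1:05d}" for i in range(config.n_kos)]
    genera = list(dict.fromkeys(lineage["genus"]))
    core = rng.dirichlet(np.ones(config.n_kos) * 0.5)
    n_spec = max(1, config.n_kos // (2 * len(genera)))
    profiles = {}
    for g in genera:
        own = rng.choice(config.n_kos, size=n_spec, replace=False)
        spec = np.zeros(config.n_kos)
        spec[own] = rng.dirichlet(np.ones(n_spec))
        profiles[g] = (1 - config.specific_frac) * core + config.specific_frac * spec
    prof = pd.DataFrame(
        [profiles[g] for g in lineage["genus"]],
        index=lineage["taxon"].to_numpy(),
        columns=kos,
    )
    levelb = rng.choice(_BRITE_B, size=config.n_kos)
    rows = []
    for i, ko in enumerate(kos):
        n_c = 1 + int(rng.random() < 0.15)  # some KOs sit in two level-C entries
        cs = rng.choice(np.arange(60), size=n_c, replace=False)
        for c in cs:
            rows.append({"ko": ko, "level_b": levelb[i], "level_c": f"{levelb[i]} C{c + 1:02d}"})
    brite = pd.DataFrame(rows)
    return prof, brite


def generate_ko(
    taxa_counts: pd.DataFrame,
    genome_profiles: pd.DataFrame,
    depth: int = 50000,
    seed: int = 0,
) -> pd.DataFrame:
    """KO counts: multinomial draws from the taxa-abundance-weighted
    mixture of genome profiles, one library per sample."""
    if not np.allclose(genome_profiles.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("genome profile rows must each sum to 1")
    missing = set(taxa_counts.columns) - set(genome_profiles.index)
    if missing:
        raise ValueError(f"no genome profile for taxa: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    P = genome_profiles.loc[taxa_counts.columns].to_numpy()
    rel = taxa_counts.to_numpy(dtype=float)
    rel = rel / rel.sum(axis=1, keepdims=True)
    mix = rel @ P
    mix = mix / mix.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, p) for p in mix])
    out = pd.DataFrame(counts, index=taxa_counts.index, columns=genome_profiles.columns)
    out.index.name = "sample_id"
    return out


# --------------------------------------------------------------------------- one-call study


@dataclass
class StudyData:
    """Everything one simulated study produces."""

    meta: pd.DataFrame  # injection-level metadata (study + qc + blank)
    study_meta: pd.DataFrame  # study samples only
    matrix: pd.DataFrame  # raw metabolite intensities, injections x features
    annotations: pd.DataFrame
    truth: DriftTruth
    layout: WorklistLayout
    taxa: pd.DataFrame
    lineage: pd.DataFrame
    taxa_base_props: np.ndarray
    ko: pd.DataFrame
    genome_profiles: pd.DataFrame
    brite: pd.DataFrame


def simulate_study(
    cohort: CohortConfig | None = None,
    taxa_config: TaxaConfig | None = None,
    ko_config: KOConfig | None = None,
    n_features: int = 150,
    seed: int = 0,
    **truth_kwargs,
) -> StudyData:
    """Simulate a full three-generation study under one master seed.

    The seed is fanned out through :class:`numpy.random.SeedSequence`
    substreams so each omic layer is independently reproducible.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    cohort = cohort or CohortConfig(seed=seeds[0])
    cohort = dataclasses.replace(cohort, seed=seeds[0])
    taxa_config = taxa_config or TaxaConfig()
    ko_config = ko_config or KOConfig()

    study_meta = generate_cohort(cohort)
    layout = build_worklist(study_meta, seed=seeds[1])
    truth = make_drift_truth(n_features=n_features, seed=seeds[2], **truth_kwargs)
    matrix = generate_metabolome(truth, layout, study_meta, seed=seeds[3])
    taxa, lineage, props = generate_taxa(study_meta, taxa_config, seed=seeds[4])
    rng = np.random.default_rng(seeds[5])
    profiles, brite = make_genome_profiles(lineage, ko_config, rng)
    ko = generate_ko(taxa, profiles, depth=ko_config.depth,
                     seed=int(rng.integers(2**31)))
    return StudyData(
        meta=layout.table.copy(),
        study_meta=study_meta,
        matrix=matrix,
        annotations=truth.annotations,
        truth=truth,
        layout=layout,
        taxa=taxa,
        lineage=lineage,
        taxa_base_props=props,
        ko=ko,
        genome_profiles=profiles,
        brite=brite,
    )
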