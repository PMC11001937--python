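"""End-to-end orchestration: simulate -> QA -> normalize -> chemometrics
-> mixed-model statistics -> ratios -> ecology -> functional profiles ->
associations -> enrichment -> multiblock integration.

Each stage consumes and produces declared DataFrames; everything written
to the output directory is checksummed into a :class:`RunManifest`, so a
rerun with the same config and seed must reproduce every checksum.  The
master seed is fanned out through ``numpy.random.SeedSequence`` so each
stage has its own reproducible substream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import associations as assoc
from . import chemometrics as chem
from . import ecology, functional, integration, lmm, normalize, qa, ratios, synth


@dataclass
class PipelineConfig:
    """All tunables of one pipeline run (defaults = study-like layout)."""

    seed: int = 0
    n_per_generation: tuple = (67, 67, 63)
    n_families: int = 67
    n_features: int = 150
    n_taxa: int = 200
    n_kos: int = 500
    taxa_concentration: float = 50.0
    library_size: int = 20000
    ko_depth: int = 50000
    blank_ratio: float = 3.0
    qc_min: float = 0.50
    sample_min: float = 0.70
    rsd_threshold: float = 30.0
    knn_k: int = 5
    alpha: float = 0.05
    lm_max_sig: float = 0.10
    ncomp: int = 2
    keepX: int = 25
    cutoff: float = 0.65
    cv_folds: int = 5
    cv_repeats: int = 10
    drift_lo: float = 0.3
    drift_hi: float = 0.8

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "n_per_generation" in data:
            data["n_per_generation"] = tuple(data["n_per_generation"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_per_generation"] = list(d["n_per_generation"])
        return d


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def add(self, stage: str, files: dict, counts: dict) -> None:
        self.stages.append({"stage": stage, "files": files, "counts": counts})

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, index_label="id") -> str:
    df.to_csv(path, sep="\t", float_format="%.10g", index_label=index_label)
    return _sha(path)


def run_pipeline(config: PipelineConfig, outdir) -> RunManifest:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    (outdir / "config.yaml").write_text(cfg_text)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_text.encode()).hexdigest(),
        seed=config.seed,
    )

    # ---- simulate -----------------------------------------------------
    study = synth.simulate_study(
        cohort=synth.CohortConfig(
            n_per_generation=tuple(config.n_per_generation),
            n_families=config.n_families,
        ),
        taxa_config=synth.TaxaConfig(
            n_taxa=config.n_taxa,
            concentration=config.taxa_concentration,
            library_size=config.library_size,
        ),
        ko_config=synth.KOConfig(n_kos=config.n_kos, depth=config.ko_depth),
        n_features=config.n_features,
        seed=config.seed,
        drift_lo=config.drift_lo,
        drift_hi=config.drift_hi,
    )
    files = {
        "metadata.tsv": _write(study.meta.set_index("sample_id"),
                               outdir / "metadata.tsv", "sample_id"),
        "matrix_raw.tsv": _write(study.matrix, outdir / "matrix_raw.tsv",
                                 "sample_id"),
        "annotations.tsv": _write(study.annotations.set_index("feature"),
                                  outdir / "annotations.tsv", "feature"),
        "taxa.tsv": _write(study.taxa, outdir / "taxa.tsv", "sample_id"),
        "lineage.tsv": _write(study.lineage.set_index("taxon"),
                              outdir / "lineage.tsv", "taxon"),
        "ko.tsv": _write(study.ko, outdir / "ko.tsv", "sample_id"),
        "brite.tsv": _write(study.brite.set_index("ko"),
                            outdir / "brite.tsv", "ko"),
        "ground_truth.tsv": _write(
            pd.DataFrame(
                {
                    "feature": study.truth.features,
                    "informative": study.truth.informative,
                    "contaminant": study.truth.contaminant,
                    "effect_infant": study.truth.gen_effects[:, 0],
                    "effect_mother": study.truth.gen_effects[:, 1],
                    "effect_grandmother": study.truth.gen_effects[:, 2],
                    "family_sd": study.truth.family_sd,
                    "residual_sd": study.truth.residual_sd,
                    "missing_rate": study.truth.missing_rate,
                    "blank_background": study.truth.blank_background,
                }
            ).set_index("feature"),
            outdir / "ground_truth.tsv",
            "feature",
        ),
    }
    manifest.add(
        "simulate",
        files,
        {
            "study_samples": int(len(study.study_meta)),
            "injections": int(len(study.meta)),
            "features": int(study.matrix.shape[1]),
            "taxa": int(study.taxa.shape[1]),
            "kos": int(study.ko.shape[1]),
        },
    )
    meta = study.meta

    # ---- QA -----------------------------------------------------------
    qa_matrix, qa_report = qa.run_qa(
        study.matrix, meta,
        blank_ratio=config.blank_ratio,
        qc_min=config.qc_min,
        sample_min=config.sample_min,
        rsd_threshold=config.rsd_threshold,
    )
    qa_rows = pd.DataFrame(
        [{"stage": k, "features": v} for k, v in qa_report.stage_counts.items()]
    ).set_index("stage")
    files = {"qa_counts.tsv": _write(qa_rows, outdir / "qa_counts.tsv", "stage")}
    manifest.add("qa", files, {k: int(v) for k, v in qa_report.stage_counts.items()})
    manifest.warnings.extend(qa_report.flags)

    # ---- normalization ------------------------------------------------
    norm_matrix, norm_info = normalize.normalize_pipeline(qa_matrix, meta)
    post_any = qa.rsd_filter(norm_matrix, meta, config.rsd_threshold, "any")
    post_all = qa.rsd_filter(norm_matrix, meta, config.rsd_threshold, "all")
    pre_all = qa_report.stage_counts.get("rsd_all_batches_reference", 0)
    files = {
        "matrix_normalized.tsv": _write(norm_matrix,
                                        outdir / "matrix_normalized.tsv",
                                        "sample_id")
    }
    manifest.add(
        "normalize",
        files,
        {
            "features_in": int(qa_matrix.shape[1]),
            "features_out": int(norm_matrix.shape[1]),
            "qcnorm_dropped": len(norm_info["qcnorm_dropped"]),
            "rsd_any_batch_post": int(post_any.shape[1]),
            "rsd_all_batches_pre": int(pre_all),
            "rsd_all_batches_post": int(post_all.shape[1]),
        },
    )

    # ---- chemometrics -------------------------------------------------
    roles = meta.set_index("sample_id").loc[study.matrix.index, "role"]
    not_blank = (roles != "blank").to_numpy()
    pre_block = normalize.knn_impute(
        study.matrix.loc[not_blank, qa_matrix.columns], k=config.knn_k
    )
    post_block = normalize.knn_impute(norm_matrix.loc[not_blank], k=config.knn_k)
    pca_pre = chem.pca(chem.uv_scale(pre_block), ncomp=config.ncomp)
    pca_post = chem.pca(chem.uv_scale(post_block), ncomp=config.ncomp)
    disp_pre = chem.qc_dispersion(pca_pre, roles[not_blank])
    disp_post = chem.qc_dispersion(pca_post, roles[not_blank])

    study_mask = (roles == "study").to_numpy()
    study_block = normalize.knn_impute(
        norm_matrix.loc[study_mask], k=config.knn_k
    )
    gens = meta.set_index("sample_id").loc[study_block.index, "generation"]
    pls = chem.plsda(chem.uv_scale(study_block), gens, ncomp=config.ncomp,
                     seed=config.seed)
    files = {
        "pca_scores_post.tsv": _write(pca_post.scores,
                                      outdir / "pca_scores_post.tsv",
                                      "sample_id"),
        "plsda_scores.tsv": _write(pls.scores, outdir / "plsda_scores.tsv",
                                   "sample_id"),
    }
    manifest.add(
        "chemometrics",
        files,
        {
            "qc_dispersion_pre": round(float(disp_pre), 6),
            "qc_dispersion_post": round(float(disp_post), 6),
            "plsda_q2": round(float(pls.q2), 6),
            "plsda_r2_total": round(float(pls.r2.sum()), 6),
        },
    )

    # ---- univariate statistics ---------------------------------------
    study_meta_idx = meta[meta["role"] == "study"]
    stats = lmm.fit_lmm_matrix(study_block, study_meta_idx, alpha=config.alpha)
    sig_sets = {
        c: set(stats[(stats["contrast"] == c) & stats["significant"]]["feature"])
        for c in ("Infant-Mother", "Infant-Grandmother", "Mother-Grandmother")
    }
    venn = lmm.venn_partition(sig_sets)
    n_sig_overall = int(
        stats[(stats["contrast"] == "overall") & stats["significant"]].shape[0]
    )
    files = {"lmm_results.tsv": _write(stats.set_index("feature"),
                                       outdir / "lmm_results.tsv", "feature")}
    manifest.add(
        "stats",
        files,
        {
            "significant_overall": n_sig_overall,
            **{f"significant_{k}": len(v) for k, v in sig_sets.items()},
            "venn": venn,
        },
    )

    # ---- ratios -------------------------------------------------------
    ratio_cols = {}
    for fn, name in ((ratios.scfa_bcfa_ratio, "SCFA/BCFA"),
                     (ratios.mufa_pufa_ratio, "MUFA/PUFA")):
        try:
            ratio_cols[name] = fn(study_block)
        except KeyError as err:
            manifest.warnings.append(str(err))
    ratio_df = pd.DataFrame(ratio_cols)
    counts = {}
    if len(ratio_df):
        gm = ratio_df.groupby(gens.to_numpy()).median()
        counts = {
            name: {g: round(float(gm.loc[g, name]), 6) for g in gm.index}
            for name in ratio_df.columns
        }
        files = {"ratios.tsv": _write(ratio_df, outdir / "ratios.tsv",
                                      "sample_id")}
    else:
        files = {}
    manifest.add("ratios", files, {"group_medians": counts})

    # ---- ecology ------------------------------------------------------
    div = ecology.alpha_diversity(study.taxa)
    div["generation"] = study.study_meta.set_index("sample_id").loc[
        div.index, "generation"
    ]
    by_gen = div.groupby("generation")[["richness", "shannon"]].mean()
    phylum = ecology.aggregate_rank(study.taxa, study.lineage, "phylum")
    phylum_prop = ecology.relative_abundance(phylum)
    lumped = ecology.lump_minor(phylum_prop, div["generation"], cut=0.001)
    files = {
        "alpha_diversity.tsv": _write(div, outdir / "alpha_diversity.tsv",
                                      "sample_id"),
        "phylum_proportions.tsv": _write(lumped,
                                         outdir / "phylum_proportions.tsv",
                                         "sample_id"),
    }
    manifest.add(
        "ecology",
        files,
        {
            "mean_shannon": {g: round(float(v), 6)
                             for g, v in by_gen["shannon"].items()},
            "mean_richness": {g: round(float(v), 6)
                              for g, v in by_gen["richness"].items()},
        },
    )

    # ---- functional profiles -----------------------------------------
    ko_norm = functional.tmm_normalize(study.ko)
    brite_b = functional.aggregate_brite(study.ko, study.brite, "B")
    brite_b_norm = functional.tmm_normalize(brite_b)
    lm_res = lmm.lm_test_functional(brite_b_norm, study_meta_idx,
                                    max_sig=config.lm_max_sig)
    files = {
        "brite_b.tsv": _write(brite_b, outdir / "brite_b.tsv", "sample_id"),
        "lm_functional.tsv": _write(lm_res.set_index("feature"),
                                    outdir / "lm_functional.tsv", "feature"),
    }
    manifest.add(
        "functional",
        files,
        {
            "brite_b_categories": int(brite_b.shape[1]),
            "significant_brite_b": int(lm_res["significant"].sum()),
        },
    )

    # ---- taxa-metabolite correlation ---------------------------------
    genus = ecology.aggregate_rank(study.taxa, study.lineage, "genus")
    genus_prop = ecology.relative_abundance(genus)
    top_genera = genus_prop.mean().sort_values(ascending=False).head(8).index
    named = [m for m in synth.NAMED_FEATURES
             if m in study_block.columns and m not in synth.IS_FEATURES]
    pairs = [(g, m) for g in top_genera for m in named[:8]]
    corr = assoc.correlate_blocks(genus_prop, study_block.loc[genus_prop.index],
                                  pairs)
    files = {"correlations.tsv": _write(corr.set_index("taxon"),
                                        outdir / "correlations.tsv", "taxon")}
    manifest.add(
        "correlate",
        files,
        {"pairs": int(len(corr)),
         "significant": int((corr["q"] < config.alpha).sum())},
    )

    # ---- enrichment ---------------------------------------------------
    anno = study.annotations[study.annotations["feature"].isin(study_block.columns)]
    sets = assoc.pathway_sets_from_annotations(anno)
    hits = {
        f for f in stats[(stats["contrast"] == "overall") & stats["significant"]]
        ["feature"] if f in set(anno["feature"])
    }
    enr = assoc.enrich_all(hits, sets)
    files = {"enrichment.tsv": _write(enr.set_index("pathway"),
                                      outdir / "enrichment.tsv", "pathway")}
    manifest.add(
        "enrich",
        files,
        {"hits": len(hits),
         "significant_pathways": int((enr["q"] < config.alpha).sum())
         if len(enr) else 0},
    )

    # ---- multiblock integration --------------------------------------
    shared = study_block.index
    blocks = {
        "metabolites": study_block,
        "taxa": np.log1p(study.taxa.loc[shared]),
        "kos": np.log1p(study.ko.loc[shared]),
    }
    labels = gens
    model = integration.fit_block_splsda(
        blocks, labels, ncomp=config.ncomp, keepX=config.keepX
    )
    perf = integration.perf_cv(
        blocks, labels, ncomp=config.ncomp, keepX=config.keepX,
        folds=config.cv_folds, repeats=config.cv_repeats, seed=config.seed,
    )
    aucs = integration.auroc_table(model)
    sim = integration.similarity_matrix(model, blocks, cutoff=config.cutoff)
    sel_cols = []
    for b in model.block_names:
        sel_cols.extend([(b, v) for v in integration.selected_union(model, b)])
    sel_matrix = pd.concat(
        [blocks[b][[v]].rename(columns={v: f"{b}:{v}"}) for b, v in sel_cols],
        axis=1,
    )
    sel_scaled = chem.uv_scale(sel_matrix)
    cim = integration.cim_cluster(sel_scaled)
    newick = integration.linkage_to_newick(cim.row_linkage, cim.row_ids)
    (outdir / "cim_samples.nwk").write_text(newick + "\n")
    corr1 = model.block_score_correlations(0)
    files = {
        "integration_scores.tsv": _write(
            pd.concat({b: model.scores[b] for b in model.block_names}, axis=1),
            outdir / "integration_scores.tsv", "sample_id"),
        "integration_auroc.tsv": _write(aucs.set_index("block"),
                                        outdir / "integration_auroc.tsv",
                                        "block"),
        "similarity_edges.tsv": _write(
            sim.set_index("var1") if len(sim) else sim,
            outdir / "similarity_edges.tsv", "var1"),
        "cim_matrix.tsv": _write(cim.matrix, outdir / "cim_matrix.tsv",
                                 "sample_id"),
        "cim_samples.nwk": _sha(outdir / "cim_samples.nwk"),
        "perf_cv.tsv": _write(perf, outdir / "perf_cv.tsv", "component"),
    }
    infant_auc = aucs[aucs["contrast"] == "Infant vs Others"]["auc"]
    manifest.add(
        "integrate",
        files,
        {
            "selected_per_block_comp1": {
                b: len(model.selected[b][0]) for b in model.block_names
            },
            "crossblock_corr_comp1_min": round(
                float(corr1.to_numpy()[np.triu_indices(len(corr1), 1)].min()), 6
            ),
            "infant_vs_others_auc_min": round(float(infant_auc.min()), 6),
            "cv_error_final": round(float(perf["mean_error"].iloc[-1]), 6),
            "similarity_edges": int(len(sim)),
        },
    )

    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    (outdir / "report.txt").write_text(report(manifest) + "\n")
    return manifest


def report(manifest: RunManifest) -> str:
    """Human-readable run summary reconciled with the manifest counts."""
    lines = [
        f"pipeline run (seed={manifest.seed}, config {manifest.config_hash[:12]})",
        "",
    ]
    for st in manifest.stages:
        lines.append(f"[{st['stage']}]")
        for k, v in st["counts"].items():
            lines.append(f"  {k}: {v}")
    if manifest.warnings:
        lines.append("")
        lines.append("warnings:")
        lines.extend(f"  - {w}" for w in manifest.warnings)
    return "\n".join(lines)
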