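"""Generator behavior: cohort layout, worklist invariants, drift-curve
ground truth, community composition, and KO mixtures."""

import numpy as np
import pandas as pd
import pytest

from triomics import ecology, synth


class TestCohort:
    def test_default_counts_and_single_generation_batches(self):
        meta = synth.generate_cohort(synth.CohortConfig(seed=0))
        assert len(meta) == 67 + 67 + 63
        per_batch = meta.groupby("batch")["generation"].nunique()
        assert (per_batch == 1).all()
        assert meta[meta["batch"] == 1]["generation"].iloc[0] == "Mother"
        assert (meta[meta["generation"] == "Mother"].shape[0],
                meta[meta["generation"] == "Grandmother"].shape[0],
                meta[meta["generation"] == "Infant"].shape[0]) == (67, 63, 67)

    def test_minimal_cohort(self):
        meta = synth.generate_cohort(
            synth.CohortConfig(n_per_generation=(1, 1, 1), n_families=1)
        )
        assert len(meta) == 3
        assert meta["family"].nunique() == 1

    def test_family_links_triads(self):
        meta = synth.generate_cohort(synth.CohortConfig(seed=3))
        by_fam = meta.groupby("family")["generation"].nunique()
        # no family holds two members of the same generation
        dup = meta.groupby(["family", "generation"]).size()
        assert (dup == 1).all()
        assert by_fam.max() == 3

    def test_too_few_families_rejected(self):
        with pytest.raises(ValueError, match="n_families"):
            synth.CohortConfig(n_per_generation=(10, 10, 10), n_families=5)

    def test_determinism(self):
        a = synth.generate_cohort(synth.CohortConfig(seed=7))
        b = synth.generate_cohort(synth.CohortConfig(seed=7))
        pd.testing.assert_frame_equal(a, b)


class TestWorklist:
    def test_layout_invariants(self):
        meta = synth.generate_cohort(synth.CohortConfig(seed=0))
        layout = synth.build_worklist(meta, seed=1)
        layout.validate()
        for _, sub in layout.table.groupby("batch"):
            qcs = sub[sub["role"] == "qc"]
            assert len(qcs) == 11
            assert (qcs["qc_kind"] == "equilibrium").sum() == 3
            # equilibrium QCs open the batch
            assert qcs[qcs["qc_kind"] == "equilibrium"]["injection_order"].max() == 3

    def test_interspersed_spacing(self):
        meta = synth.generate_cohort(synth.CohortConfig(seed=0))
        layout = synth.build_worklist(meta, seed=1)
        sub = layout.table[layout.table["batch"] == 1]
        pos = sub[(sub["role"] == "qc") & (sub["qc_kind"] == "interspersed")][
            "injection_order"
        ].to_numpy()
        gaps = np.diff(pos)
        assert gaps.min() >= 8 and gaps.max() <= 11


class TestMetabolome:
    def _small(self, **kw):
        cfg = synth.CohortConfig(n_per_generation=(6, 6, 6), n_families=6, seed=0)
        meta = synth.generate_cohort(cfg)
        layout = synth.build_worklist(meta, seed=0)
        truth = synth.make_drift_truth(n_features=20, seed=0, **kw)
        return meta, layout, truth

    def test_zero_drift_zero_noise_qcs_identical(self):
        meta, layout, truth = self._small()
        truth.drift_slope[:] = 0.0
        truth.drift_amp[:] = 0.0
        truth.qc_noise_cv = 0.0
        mat = synth.generate_metabolome(truth, layout, meta, seed=0)
        roles = layout.table.set_index("sample_id")["role"]
        qc = mat.loc[roles[roles == "qc"].index]
        batches = layout.table.set_index("sample_id")["batch"]
        for b in (1, 2, 3):
            sub = qc.loc[[i for i in qc.index if batches[i] == b]]
            assert np.allclose(sub.to_numpy(), sub.to_numpy()[0])

    def test_linear_drift_truth_curve(self):
        """Injected drift 1 + slope*(o/n): at half the run a slope of 1.0
        gives 1.5x the order-0 baseline, by direct curve evaluation."""
        meta, layout, truth = self._small()
        truth.drift_slope[:] = 0.5
        truth.drift_amp[:] = 0.0
        n = 100
        curve = truth.drift_curve(0, 0, np.array([0, 50, 100]), n)
        assert np.allclose(curve, [1.0, 1.25, 1.5])

    def test_blank_rows_only_background(self):
        meta, layout, truth = self._small()
        truth.blank_background[:] = 0.0
        mat = synth.generate_metabolome(truth, layout, meta, seed=0)
        roles = layout.table.set_index("sample_id")["role"]
        blanks = mat.loc[roles[roles == "blank"].index]
        assert (blanks.to_numpy() == 0).all()

    def test_layout_meta_mismatch_rejected(self):
        meta, layout, truth = self._small()
        with pytest.raises(ValueError, match="different study samples"):
            synth.generate_metabolome(truth, layout, meta.iloc[:-2], seed=0)

    def test_null_features_have_zero_effects(self):
        _, _, truth = self._small()
        null = ~truth.informative
        assert null.any()
        assert (truth.gen_effects[null] == 0).all()

    def test_determinism(self):
        meta, layout, truth = self._small()
        a = synth.generate_metabolome(truth, layout, meta, seed=5)
        b = synth.generate_metabolome(truth, layout, meta, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestTaxa:
    def test_infant_top3_share_exceeds_half(self):
        cfg = synth.TaxaConfig(n_taxa=80, seed=4)
        meta = synth.generate_cohort(
            synth.CohortConfig(n_per_generation=(20, 5, 5), n_families=20, seed=4)
        )
        counts, lineage, props = synth.generate_taxa(meta, cfg)
        genus_mass = pd.Series(props[0], index=lineage["genus"]).groupby(level=0).sum()
        assert genus_mass[list(synth.INFANT_TOP3)].sum() > 0.5

    def test_adult_base_shannon_exceeds_infant(self):
        """Closed form -sum p ln p on the ground-truth base proportions."""
        cfg = synth.TaxaConfig(n_taxa=80, seed=4)
        meta = synth.generate_cohort(synth.CohortConfig(seed=4))
        _, _, props = synth.generate_taxa(meta, cfg)
        H = [-np.sum(p[p > 0] * np.log(p[p > 0])) for p in props]
        assert H[1] > H[0] and H[2] > H[0]  # Mother, Grandmother > Infant

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="concentration"):
            synth.TaxaConfig(concentration=-1.0)

    def test_determinism(self):
        cfg = synth.TaxaConfig(n_taxa=40, seed=9)
        meta = synth.generate_cohort(
            synth.CohortConfig(n_per_generation=(5, 5, 5), n_families=5, seed=9)
        )
        a, _, _ = synth.generate_taxa(meta, cfg)
        b, _, _ = synth.generate_taxa(meta, cfg)
        pd.testing.assert_frame_equal(a, b)


class TestKO:
    def _profiles(self, n_taxa=3, n_kos=20, seed=0):
        rng = np.random.default_rng(seed)
        lineage = pd.DataFrame(
            {"taxon": [f"T{i}" for i in range(n_taxa)],
             "genus": [f"G{i}" for i in range(n_taxa)]}
        )
        prof = rng.dirichlet(np.ones(n_kos), size=n_taxa)
        return pd.DataFrame(prof, index=lineage["taxon"].to_numpy(),
                            columns=[f"K{i:05d}" for i in range(n_kos)])

    def test_single_taxon_community_matches_profile(self):
        prof = self._profiles(n_taxa=1)
        counts = pd.DataFrame({"T0": [100000]}, index=["S1"])
        ko = synth.generate_ko(counts, prof, depth=2_000_00, seed=0)
        got = ko.iloc[0] / ko.iloc[0].sum()
        assert np.abs(got.to_numpy() - prof.iloc[0].to_numpy()).max() < 0.01

    def test_two_taxa_mixture_average(self):
        """Disjoint 50/50 profiles: expected KO proportions are the plain
        average of the two genome profiles (mixture arithmetic)."""
        p = np.zeros((2, 10))
        p[0, :5] = 0.2
        p[1, 5:] = 0.2
        prof = pd.DataFrame(p, index=["T0", "T1"],
                            columns=[f"K{i}" for i in range(10)])
        counts = pd.DataFrame({"T0": [5000], "T1": [5000]}, index=["S1"])
        ko = synth.generate_ko(counts, prof, depth=500000, seed=1)
        got = ko.iloc[0] / ko.iloc[0].sum()
        expected = p.mean(axis=0)
        assert np.abs(got.to_numpy() - expected).max() < 0.005

    def test_unnormalized_profiles_rejected(self):
        prof = self._profiles() * 2.0
        counts = pd.DataFrame({c: [10] for c in prof.index}, index=["S1"])
        with pytest.raises(ValueError, match="sum to 1"):
            synth.generate_ko(counts, prof)

    def test_determinism(self):
        prof = self._profiles()
        counts = pd.DataFrame(
            [[10, 20, 30]], index=["S1"], columns=prof.index
        )
        a = synth.generate_ko(counts, prof, depth=1000, seed=3)
        b = synth.generate_ko(counts, prof, depth=1000, seed=3)
        pd.testing.assert_frame_equal(a, b)


def test_simulate_study_deterministic(small_study):
    again = synth.simulate_study(
        cohort=synth.CohortConfig(n_per_generation=(24, 24, 21), n_families=24),
        taxa_config=synth.TaxaConfig(n_taxa=80, library_size=8000),
        ko_config=synth.KOConfig(n_kos=150, depth=15000),
        n_features=60,
        seed=11,
    )
    pd.testing.assert_frame_equal(small_study.matrix, again.matrix)
    pd.testing.assert_frame_equal(small_study.taxa, again.taxa)
    pd.testing.assert_frame_equal(small_study.ko, again.ko)


def test_null_features_equal_group_means_in_expectation(small_study):
    """Monte Carlo over study samples: features with zero true effect show
    no systematic generation difference (on the log scale, pooled)."""
    s = small_study
    roles = s.meta.set_index("sample_id")["role"]
    study = s.matrix.loc[roles[roles == "study"].index]
    gens = s.meta.set_index("sample_id").loc[study.index, "generation"]
    null = [f for f, inf, cont in zip(
        s.truth.features, s.truth.informative, s.truth.contaminant)
        if not inf and not cont]
    # remove drift/batch structure using the known truth before comparing
    logs = np.log(study[null]).groupby(gens.to_numpy()).mean()
    spread = (logs.max() - logs.min())
    # batch factors differ per generation-batch; compare against their
    # known log-scale spread plus sampling noise
    truth_spread = np.ptp(
        np.log(s.truth.batch_factor), axis=1
    )[[s.truth.features.index(f) for f in null]]
    assert float((spread.to_numpy() - truth_spread).mean()) < 0.2
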