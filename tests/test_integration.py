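"""Multiblock sparse PLS-DA: sparsity contract, planted-variable
recovery, CV behavior, AUROC oracle, similarity cutoff, and CIM
clustering against hand-computed linkage."""

import numpy as np
import pandas as pd
import pytest

from triomics import integration as integ


def make_blocks(n_per_class=30, p=60, n_informative=10, delta=2.0, seed=0,
                shared_latent=True):
    """Three classes; each block carries `n_informative` planted
    discriminant variables driven by shared class-dependent latents."""
    rng = np.random.default_rng(seed)
    classes = np.repeat(["Infant", "Mother", "Grandmother"], n_per_class)
    n = len(classes)
    ids = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    latent = np.zeros((n, 2))
    latent[classes == "Infant", 0] = delta
    latent[classes == "Grandmother", 1] = delta
    latent += 0.3 * rng.normal(size=(n, 2))
    blocks, planted = {}, {}
    for b in ("X1", "X2", "X3"):
        X = rng.normal(size=(n, p))
        idx = rng.choice(p, n_informative, replace=False)
        for j, col in enumerate(idx):
            X[:, col] += latent[:, j % 2] * rng.choice([-1, 1])
        blocks[b] = pd.DataFrame(X, index=ids,
                                 columns=[f"{b}v{i}" for i in range(p)])
        planted[b] = {f"{b}v{i}" for i in idx}
    return blocks, pd.Series(classes, index=ids), planted


class TestFit:
    def test_identical_blocks_perfect_score_correlation(self):
        blocks, labels, _ = make_blocks(seed=1)
        dup = {"A": blocks["X1"],
               "B": blocks["X1"].copy().rename(columns=lambda c: c + "_b")}
        model = integ.fit_block_splsda(dup, labels, ncomp=1, keepX=25)
        corr = model.block_score_correlations(0)
        assert corr.loc["A", "B"] == pytest.approx(1.0, abs=1e-8)

    def test_exactly_keepx_nonzero_loadings(self):
        blocks, labels, _ = make_blocks(seed=2)
        model = integ.fit_block_splsda(blocks, labels, ncomp=2, keepX=25)
        for b in model.block_names:
            L = model.loadings[b].to_numpy()
            for h in range(2):
                assert (L[:, h] != 0).sum() == 25

    def test_planted_variables_recovered(self):
        """>= 8/10 planted discriminant variables land in the selected
        sets, averaged over replicates."""
        rates = []
        for seed in range(10):
            blocks, labels, planted = make_blocks(seed=seed)
            model = integ.fit_block_splsda(blocks, labels, ncomp=2, keepX=25)
            for b in model.block_names:
                sel = set().union(*model.selected[b])
                rates.append(len(sel & planted[b]) / len(planted[b]))
        assert np.mean(rates) >= 0.8

    def test_deflation_orthogonality(self):
        blocks, labels, _ = make_blocks(seed=3)
        model = integ.fit_block_splsda(blocks, labels, ncomp=3, keepX=20)
        for b in model.block_names:
            T = model.scores[b].to_numpy()
            G = T.T @ T
            off = G - np.diag(np.diag(G))
            assert np.abs(off).max() < 1e-6 * np.abs(np.diag(G)).max()

    def test_keepx_exceeding_width_rejected(self):
        blocks, labels, _ = make_blocks(p=10, n_informative=3, seed=4)
        with pytest.raises(ValueError, match="keepX"):
            integ.fit_block_splsda(blocks, labels, keepX=25)

    def test_single_class_rejected(self):
        blocks, labels, _ = make_blocks(seed=5)
        with pytest.raises(ValueError, match="two classes"):
            integ.fit_block_splsda(blocks, ["A"] * len(labels))

    def test_determinism(self):
        blocks, labels, _ = make_blocks(seed=6)
        a = integ.fit_block_splsda(blocks, labels, ncomp=2, keepX=15)
        b = integ.fit_block_splsda(blocks, labels, ncomp=2, keepX=15)
        for name in a.block_names:
            pd.testing.assert_frame_equal(a.loadings[name], b.loadings[name])


class TestPerfCV:
    def test_separated_classes_error_near_zero(self):
        blocks, labels, _ = make_blocks(delta=4.0, seed=7)
        perf = integ.perf_cv(blocks, labels, ncomp=2, keepX=15, folds=5,
                             repeats=2, seed=0)
        assert perf["mean_error"].iloc[-1] < 0.05

    def test_permuted_labels_error_near_chance(self):
        blocks, labels, _ = make_blocks(delta=3.0, seed=8)
        rng = np.random.default_rng(0)
        perm = pd.Series(rng.permutation(labels.to_numpy()),
                         index=labels.index)
        perf = integ.perf_cv(blocks, perm, ncomp=2, keepX=15, folds=5,
                             repeats=2, seed=0)
        # chance = 1 - max class prior = 2/3 for balanced 3 classes
        assert perf["mean_error"].iloc[-1] > 0.45

    def test_same_seed_identical(self):
        blocks, labels, _ = make_blocks(seed=9)
        a = integ.perf_cv(blocks, labels, ncomp=1, keepX=10, repeats=2, seed=3)
        b = integ.perf_cv(blocks, labels, ncomp=1, keepX=10, repeats=2, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_class_smaller_than_folds_rejected(self):
        blocks, labels, _ = make_blocks(n_per_class=4, seed=10)
        with pytest.raises(ValueError, match="folds"):
            integ.perf_cv(blocks, labels, folds=5)


class TestAUROC:
    def test_perfect_separation(self):
        assert integ.auroc([1, 2, 3, 10, 11, 12],
                           [False, False, False, True, True, True]) == 1.0

    def test_tie_handling_matches_pair_counting(self):
        """4-point toy with one tie: AUC equals exhaustive counting of
        (positive > negative) pairs with ties worth 1/2."""
        scores = np.array([1.0, 2.0, 2.0, 3.0])
        pos = np.array([False, False, True, True])
        wins = 0.0
        npairs = 0
        for sp in scores[pos]:
            for sn in scores[~pos]:
                npairs += 1
                wins += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
        assert integ.auroc(scores, pos) == pytest.approx(wins / npairs)

    def test_independent_labels_near_half(self):
        rng = np.random.default_rng(0)
        aucs = [integ.auroc(rng.normal(size=200), rng.random(200) < 0.5)
                for _ in range(30)]
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            integ.auroc([1, 2], [True, True])

    def test_infant_contrast_high_on_separated_blocks(self):
        blocks, labels, _ = make_blocks(delta=3.0, seed=11)
        model = integ.fit_block_splsda(blocks, labels, ncomp=2, keepX=15)
        for b in model.block_names:
            assert integ.auroc_block(model, b, "Infant") > 0.95


class TestSimilarity:
    def test_cutoff_rule(self):
        blocks, labels, _ = make_blocks(delta=3.0, seed=12)
        model = integ.fit_block_splsda(blocks, labels, ncomp=2, keepX=10)
        lo = integ.similarity_matrix(model, blocks, cutoff=0.60)
        hi = integ.similarity_matrix(model, blocks, cutoff=0.70)
        assert (lo["similarity"].abs() > 0.60).all()
        assert len(hi) <= len(lo)
        # an edge between 0.60 and 0.70 appears only at the lower cutoff
        mid = lo[(lo["similarity"].abs() > 0.60)
                 & (lo["similarity"].abs() <= 0.70)]
        if len(mid):
            merged = mid.merge(hi, on=["var1", "var2"], how="inner")
            assert merged.empty

    def test_no_self_pairs(self):
        blocks, labels, _ = make_blocks(delta=3.0, seed=13)
        model = integ.fit_block_splsda(blocks, labels, ncomp=2, keepX=10)
        sim = integ.similarity_matrix(model, blocks, cutoff=0.0,
                                      include_within=True)
        assert not ((sim["var1"] == sim["var2"])
                    & (sim["block1"] == sim["block2"])).any()

    def test_coregulated_pair_linked(self):
        """Two variables driven by the same latent in different blocks
        get a positive link above the cutoff in nearly all replicates."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 90
            classes = np.repeat(["A", "B", "C"], 30)
            latent = (classes == "A") * 2.5 + 0.3 * rng.normal(size=n)
            ids = pd.Index([f"s{i}" for i in range(n)])
            X1 = pd.DataFrame(rng.normal(size=(n, 20)), index=ids,
                              columns=[f"a{i}" for i in range(20)])
            X2 = pd.DataFrame(rng.normal(size=(n, 20)), index=ids,
                              columns=[f"b{i}" for i in range(20)])
            X1["a0"] += latent
            X2["b0"] += latent
            blocks = {"X1": X1, "X2": X2}
            model = integ.fit_block_splsda(blocks, pd.Series(classes, index=ids),
                                           ncomp=2, keepX=5)
            sim = integ.similarity_matrix(model, blocks, cutoff=0.65)
            link = sim[(sim["var1"] == "a0") & (sim["var2"] == "b0")]
            if len(link) and (link["similarity"] > 0.65).all():
                hits += 1
        assert hits >= 9


class TestCIM:
    def test_four_point_complete_linkage_enumeration(self):
        """Merge order checked against a hand-computed complete-linkage
        table: {a,b} at 1, {c,d} at 2, then everything at 10."""
        mat = pd.DataFrame(
            {"x": [0.0, 1.0, 10.0, 12.0]},
            index=["a", "b", "c", "d"],
        )
        cim = integ.cim_cluster(mat)
        Z = cim.row_linkage
        assert Z[0, 2] == pytest.approx(1.0)  # a-b
        assert Z[1, 2] == pytest.approx(2.0)  # c-d
        assert Z[2, 2] == pytest.approx(12.0)  # max(|0-12|,...) = 12
        lab = cim.cut_rows(2)
        assert lab["a"] == lab["b"] and lab["c"] == lab["d"]
        assert lab["a"] != lab["c"]

    def test_duplicate_rows_merge_first_at_zero(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.normal(size=(5, 3)),
                           index=list("abcde"))
        mat.loc["e"] = mat.loc["a"]
        cim = integ.cim_cluster(mat)
        assert cim.row_linkage[0, 2] == 0.0

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="two rows"):
            integ.cim_cluster(pd.DataFrame({"x": [1.0]}))

    def test_newick_roundtrip_leaf_names(self):
        mat = pd.DataFrame({"x": [0.0, 1.0, 5.0]}, index=["a", "b", "c"])
        cim = integ.cim_cluster(mat)
        nwk = integ.linkage_to_newick(cim.row_linkage, cim.row_ids)
        assert nwk.endswith(";")
        for leaf in "abc":
            assert leaf in nwk


def test_single_block_reduces_to_pls(ncomp=1):
    """With one block (design weight irrelevant), the first component
    direction matches sklearn's PLS against the dummy outcome."""
    from sklearn.cross_decomposition import PLSRegression

    rng = np.random.default_rng(14)
    n = 60
    classes = np.repeat(["A", "B"], 30)
    X = rng.normal(size=(n, 12))
    X[classes == "B", :3] += 1.5
    ids = pd.Index([f"s{i}" for i in range(n)])
    Xdf = pd.DataFrame(X, index=ids)
    Xdf.columns = [f"v{i}" for i in range(12)]
    model = integ.fit_block_splsda({"X": Xdf}, pd.Series(classes, index=ids),
                                   ncomp=1, keepX=12)
    Y = np.stack([(classes == "A").astype(float),
                  (classes == "B").astype(float)], 1)
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    pls = PLSRegression(n_components=1, scale=False).fit(Xs, Y - Y.mean(0))
    w_ref = pls.x_weights_[:, 0]
    w = model.loadings["X"].iloc[:, 0].to_numpy()
    cos = abs(w @ w_ref) / (np.linalg.norm(w) * np.linalg.norm(w_ref))
    assert cos > 0.999
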