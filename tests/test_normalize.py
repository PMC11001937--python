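"""Drift-correction behavior: QC-SVRC curve recovery, QC-Norm scaling
arithmetic, and KNN imputation against a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from triomics import normalize, qa
from conftest import toy_meta


def _batch_with_qcs(n_inj=60, qc_every=8):
    orders = np.arange(1, n_inj + 1)
    qc_mask = (orders % qc_every) == 0
    return orders, qc_mask


class TestQCSVRC:
    def test_constant_qcs_identity(self):
        orders, qc_mask = _batch_with_qcs()
        mat = pd.DataFrame({"f": np.full(len(orders), 500.0)},
                           index=[f"I{o}" for o in orders])
        model = normalize.qc_svrc_fit(mat, qc_mask, orders)
        out = normalize.qc_svrc_apply(mat, model, orders)
        assert np.allclose(out["f"], mat["f"])

    def test_linear_drift_recovered_within_one_percent(self):
        orders, qc_mask = _batch_with_qcs()
        true = 1000.0 * (1 + 0.01 * orders)
        mat = pd.DataFrame({"f": true}, index=[f"I{o}" for o in orders])
        model = normalize.qc_svrc_fit(mat, qc_mask, orders)
        curve = model.curves[("f", 0)]
        pred = curve.predict(orders[qc_mask])
        assert np.abs(pred / true[qc_mask] - 1).max() < 0.01

    def test_too_few_qcs_error(self):
        orders = np.arange(1, 20)
        qc_mask = np.zeros(len(orders), dtype=bool)
        qc_mask[[5, 10]] = True
        mat = pd.DataFrame({"f": np.ones(len(orders))},
                           index=[f"I{o}" for o in orders])
        with pytest.raises(normalize.DriftError, match="at least 5"):
            normalize.qc_svrc_fit(mat, qc_mask, orders)

    def test_correction_flattens_drifted_qcs(self):
        rng = np.random.default_rng(0)
        orders, qc_mask = _batch_with_qcs()
        drift = 1 + 0.012 * orders
        noise = np.exp(rng.normal(0, 0.02, len(orders)))
        mat = pd.DataFrame({"f": 800.0 * drift * noise},
                           index=[f"I{o}" for o in orders])
        model = normalize.qc_svrc_fit(mat, qc_mask, orders)
        out = normalize.qc_svrc_apply(mat, model, orders)
        rsd_pre = qa.compute_rsd(mat.loc[qc_mask, "f"])
        rsd_post = qa.compute_rsd(out.loc[qc_mask, "f"])
        assert rsd_post < rsd_pre
        assert rsd_post < 5.0  # noise CV was 2%

    def test_corrected_levels_near_qc_reference(self):
        orders, qc_mask = _batch_with_qcs()
        drift = 1 + 0.01 * orders
        mat = pd.DataFrame({"f": 100.0 * drift},
                           index=[f"I{o}" for o in orders])
        model = normalize.qc_svrc_fit(mat, qc_mask, orders)
        out = normalize.qc_svrc_apply(mat, model, orders)
        ref = model.curves[("f", 0)].reference
        assert abs(out["f"].mean() / ref - 1) < 0.05


class TestQCNorm:
    def _two_batch(self, qc_values):
        frames = []
        for b, vals in enumerate(qc_values, start=1):
            m = toy_meta(n_study=1, n_qc=len(vals), n_blank=0, batch=b)
            m["sample_id"] = m["sample_id"] + f"_b{b}"
            frames.append(m)
        meta = pd.concat(frames, ignore_index=True)
        col = []
        for vals in qc_values:
            col.extend(vals)
            col.append(150.0)  # study sample
        mat = pd.DataFrame({"f": col}, index=meta["sample_id"].to_numpy())
        return mat, meta

    def test_equal_medians_identity(self):
        mat, meta = self._two_batch([(100, 100, 100), (100, 100, 100)])
        out, dropped = normalize.qc_norm(mat, meta)
        assert not dropped
        pd.testing.assert_frame_equal(out, mat)

    def test_scaling_arithmetic(self):
        """Batch QC medians 200 and 100; the grand median of all six QCs
        is 150, so the batches scale by 0.75 and 1.5."""
        mat, meta = self._two_batch([(200, 200, 200), (100, 100, 100)])
        out, _ = normalize.qc_norm(mat, meta)
        b1 = out.loc[[i for i in out.index if i.endswith("b1")], "f"]
        b2 = out.loc[[i for i in out.index if i.endswith("b2")], "f"]
        assert np.allclose(b1.iloc[:3], 150.0)  # 200 * 0.75
        assert np.allclose(b2.iloc[:3], 150.0)  # 100 * 1.5
        assert b1.iloc[3] == pytest.approx(150 * 0.75)
        assert b2.iloc[3] == pytest.approx(150 * 1.5)

    def test_qc_medians_equal_after(self, default_normalized):
        norm = default_normalized["normalized"]
        meta = default_normalized["study"].meta
        m = meta.set_index("sample_id").loc[norm.index]
        qc = qa.interspersed_qc_mask(meta, norm)
        med_by_batch = norm.iloc[qc].groupby(
            m["batch"].to_numpy()[qc]
        ).median()
        spread = (med_by_batch.max() - med_by_batch.min()) / med_by_batch.mean()
        assert float(spread.max()) < 1e-9

    def test_nonpositive_median_drops_feature(self):
        mat, meta = self._two_batch([(0, 0, 0), (100, 100, 100)])
        out, dropped = normalize.qc_norm(mat, meta)
        assert dropped == ["f"]
        assert out.shape[1] == 0

    def test_commutes_with_feature_rescaling(self):
        mat, meta = self._two_batch([(80, 100, 120), (40, 50, 60)])
        out1, _ = normalize.qc_norm(mat * 7.0, meta)
        out2, _ = normalize.qc_norm(mat, meta)
        pd.testing.assert_frame_equal(out1, out2 * 7.0)


class TestKNNImpute:
    def test_no_missing_identity(self):
        mat = pd.DataFrame(np.arange(12.0).reshape(4, 3),
                           index=list("abcd"), columns=list("xyz"))
        pd.testing.assert_frame_equal(normalize.knn_impute(mat, k=2), mat)

    def test_duplicate_neighbor_k1(self):
        mat = pd.DataFrame(
            {"x": [1.0, 1.0, 50.0], "y": [2.0, 2.0, 60.0],
             "z": [3.0, np.nan, 70.0]},
            index=["a", "dup", "far"],
        )
        out = normalize.knn_impute(mat, k=1)
        assert out.loc["dup", "z"] == pytest.approx(3.0)
        # observed entries untouched
        assert out.loc["far", "z"] == 70.0

    def test_three_sample_toy_vs_bruteforce(self):
        """k=2 imputation equals the mean of the two nearest samples from
        an exhaustively computed distance table on scaled data."""
        mat = pd.DataFrame(
            {"x": [1.0, 2.0, 10.0, 1.5],
             "y": [5.0, 6.0, 30.0, 5.5],
             "z": [2.0, np.nan, 9.0, 2.2]},
            index=list("abcd"),
        )
        out = normalize.knn_impute(mat, k=2)
        mu, sd = mat.mean(), mat.std(ddof=1)
        scaled = (mat - mu) / sd
        target = scaled.loc["b", ["x", "y"]].to_numpy()
        dists = {}
        for other in ["a", "c", "d"]:
            dd = scaled.loc[other, ["x", "y"]].to_numpy() - target
            # nan-euclidean convention: rescale by total/observed columns
            dists[other] = np.sqrt((dd**2).sum() * 3 / 2)
        nearest = sorted(dists, key=lambda o: dists[o])[:2]
        expected = scaled.loc[nearest, "z"].mean() * sd["z"] + mu["z"]
        assert out.loc["b", "z"] == pytest.approx(expected)

    def test_feature_all_missing_error(self):
        mat = pd.DataFrame({"x": [1.0, 2.0], "z": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="missing in every sample"):
            normalize.knn_impute(mat, k=1)

    def test_k_too_large_error(self):
        mat = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValueError, match="smaller"):
            normalize.knn_impute(mat, k=2)


def test_rsd_all_batch_pass_count_increases(default_normalized):
    """After QC-SVRC + QC-Norm, strictly more features clear the
    all-batch RSD<30% gate than before (the sensitive QA indicator)."""
    pre = default_normalized["qa_report"].stage_counts["rsd_all_batches_reference"]
    meta = default_normalized["study"].meta
    post = qa.rsd_filter(default_normalized["normalized"], meta, 30, "all")
    assert post.shape[1] > pre


def test_correction_preserves_sample_order(default_normalized):
    assert list(default_normalized["normalized"].index) == list(
        default_normalized["qa_matrix"].index
    )
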