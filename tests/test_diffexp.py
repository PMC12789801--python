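"""Design construction, per-feature OLS, eBayes moderation, BH, batch removal."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from omicweave import diffexp as de
from omicweave import preprocess as pp
from omicweave.containers import InputError, SampleAnnotation

from conftest import make_dataset


def two_group_annotation(n_per_group=2, batch=None):
    n = 2 * n_per_group
    frame = pd.DataFrame(
        {
            "sample": [f"s{j}" for j in range(n)],
            "treatment": ["vehicle"] * n_per_group + ["drug"] * n_per_group,
        }
    )
    if batch is not None:
        frame["batch"] = batch
    return SampleAnnotation.from_frame(frame)


class TestBuildDesign:
    def test_treatment_coding(self):
        annot = two_group_annotation()
        design = de.build_design(annot, ["treatment"], reference_levels={"treatment": "vehicle"})
        assert design.matrix.shape == (4, 2)
        assert design.coef_names == ["(Intercept)", "treatmentdrug"]
        np.testing.assert_array_equal(
            design.matrix["treatmentdrug"].to_numpy(), [0, 0, 1, 1]
        )

    def test_default_reference_is_lexicographic(self):
        annot = two_group_annotation()
        design = de.build_design(annot, ["treatment"])
        # "drug" < "vehicle" so vehicle becomes the indicator level
        assert design.coef_names == ["(Intercept)", "treatmentvehicle"]

    def test_batch_adds_column(self):
        annot = two_group_annotation(batch=["b1", "b2", "b1", "b2"])
        design = de.build_design(annot, ["treatment", "batch"])
        assert design.matrix.shape == (4, 3)

    def test_confounded_factor_raises_rank_error(self):
        annot = two_group_annotation(batch=["b1", "b1", "b2", "b2"])
        with pytest.raises(InputError, match="aliased"):
            de.build_design(annot, ["treatment", "batch"])

    def test_centered_covariate(self):
        frame = pd.DataFrame(
            {"sample": list("abcd"), "group": ["A", "A", "B", "B"], "age": [1, 2, 3, 6]}
        )
        design = de.build_design(SampleAnnotation.from_frame(frame), ["group"], ["age"])
        assert design.matrix["age"].sum() == pytest.approx(0.0)


class TestFitLinearModel:
    def test_balanced_two_group_by_hand(self):
        # A = [1, 3], B = [5, 7]: logFC 4, s^2 = SSE/df = 4/2 = 2
        ds = make_dataset([[1.0, 3.0, 5.0, 7.0]], groups=["A", "A", "B", "B"])
        design = de.build_design(ds.sample_meta, ["group"])
        fit = de.fit_linear_model(ds, design, "groupB")
        row = fit.table.iloc[0]
        assert row["logFC"] == pytest.approx(4.0)
        assert row["s2"] == pytest.approx(2.0)
        assert row["df_resid"] == 2
        assert row["AveExpr"] == pytest.approx(4.0)

    def test_missing_sample_reduces_df(self):
        ds = make_dataset(
            [[1.0, 3.0, 5.0, 7.0], [1.0, np.nan, 5.0, 7.0]], groups=["A", "A", "B", "B"]
        )
        design = de.build_design(ds.sample_meta, ["group"])
        fit = de.fit_linear_model(ds, design, "groupB")
        assert fit.table["df_resid"].tolist() == [2.0, 1.0]

    def test_constant_feature(self):
        ds = make_dataset([[5.0, 5.0, 5.0, 5.0]], groups=["A", "A", "B", "B"])
        design = de.build_design(ds.sample_meta, ["group"])
        fit = de.fit_linear_model(ds, design, "groupB")
        assert fit.table["logFC"].iloc[0] == pytest.approx(0.0)
        assert fit.table["s2"].iloc[0] == pytest.approx(0.0)

    def test_too_few_samples_gives_missing_coefficients(self):
        ds = make_dataset([[1.0, np.nan, np.nan, 7.0]], groups=["A", "A", "B", "B"])
        design = de.build_design(ds.sample_meta, ["group"])
        fit = de.fit_linear_model(ds, design, "groupB")
        # 2 observed points fit exactly (df 0) but remain estimable;
        # 1 observed point with 2 coefficients is not
        ds1 = make_dataset([[1.0, np.nan, np.nan, np.nan]], groups=["A", "A", "B", "B"])
        fit1 = de.fit_linear_model(ds1, design, "groupB")
        assert np.isnan(fit1.table["logFC"].iloc[0])
        assert fit.table["df_resid"].iloc[0] == 0.0

    def test_complete_balanced_logfc_is_mean_difference(self):
        rng = np.random.default_rng(9)
        values = rng.normal(20, 1, (50, 6))
        groups = ["A"] * 3 + ["B"] * 3
        ds = make_dataset(values, groups=groups)
        design = de.build_design(ds.sample_meta, ["group"])
        fit = de.fit_linear_model(ds, design, "groupB")
        expected = values[:, 3:].mean(axis=1) - values[:, :3].mean(axis=1)
        np.testing.assert_allclose(fit.table["logFC"].to_numpy(), expected, atol=1e-10)


class TestEbayes:
    def test_homogeneous_variances_give_infinite_d0(self):
        # all s2 identical -> no excess spread -> d0 = inf, s0^2 = common value
        s2 = np.full(50, 0.7)
        d0, s0 = de.fit_variance_prior(s2, np.full(50, 4.0))
        assert np.isinf(d0)
        assert s0 == pytest.approx(0.7)

    def test_parameter_recovery(self):
        from omicweave.validate import ebayes_recovery_trial

        d0_hat, s0_hat = ebayes_recovery_trial(d0=4.0, s0_sq=1.0, df=6.0, n_features=5000, seed=10)
        assert 3.0 <= d0_hat <= 5.0
        assert 0.9 <= s0_hat <= 1.1

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(12)
        values = rng.normal(20, 0.7, (2000, 8))
        ds = make_dataset(values, groups=["A"] * 4 + ["B"] * 4)
        design = de.build_design(ds.sample_meta, ["group"])
        fit = de.ebayes_moderate(de.fit_linear_model(ds, design, "groupB"))
        pvals = fit.table["P.Value"].to_numpy()
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_type_one_error_in_binomial_envelope(self):
        rng = np.random.default_rng(13)
        values = rng.normal(20, 0.7, (4000, 8))
        ds = make_dataset(values, groups=["A"] * 4 + ["B"] * 4)
        design = de.build_design(ds.sample_meta, ["group"])
        fit = de.ebayes_moderate(de.fit_linear_model(ds, design, "groupB"))
        rate = float((fit.table["P.Value"] < 0.05).mean())
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / 4000)
        assert abs(rate - 0.05) < half_width

    def test_moderated_variance_is_convex_combination(self):
        rng = np.random.default_rng(14)
        values = rng.normal(20, 1, (300, 6)) * rng.uniform(0.2, 3, (300, 1))
        ds = make_dataset(values, groups=["A"] * 3 + ["B"] * 3)
        design = de.build_design(ds.sample_meta, ["group"])
        fit = de.ebayes_moderate(de.fit_linear_model(ds, design, "groupB"))
        t = fit.table
        lo = np.minimum(t["s2"], fit.s0_sq)
        hi = np.maximum(t["s2"], fit.s0_sq)
        assert ((t["s2_post"] >= lo - 1e-12) & (t["s2_post"] <= hi + 1e-12)).all()

    def test_all_zero_variances_error(self):
        ds = make_dataset([[1.0, 1.0, 2.0, 2.0], [3.0, 3.0, 4.0, 4.0]],
                          groups=["A", "A", "B", "B"])
        design = de.build_design(ds.sample_meta, ["group"])
        fit = de.fit_linear_model(ds, design, "groupB")
        with pytest.raises(InputError):
            de.ebayes_moderate(fit)


class TestAdjustBH:
    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(
            de.adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_degenerate(self):
        assert de.adjust_bh([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(de.adjust_bh([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_nan_passthrough(self):
        out = de.adjust_bh([0.01, np.nan, 0.02])
        assert np.isnan(out[1]) and np.isfinite(out[0])

    def test_out_of_range_errors(self):
        with pytest.raises(InputError):
            de.adjust_bh([0.5, 1.2])

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(15)
        for _ in range(50):
            p = rng.random(rng.integers(1, 60))
            ours = de.adjust_bh(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_matches_bruteforce_stepup(self):
        def brute(p):
            p = np.asarray(p, float)
            n = p.size
            adj = np.empty(n)
            for i in range(n):
                # step-up: min over j with p_(j) >= p_i of p_(j)*n/j, capped
                candidates = [
                    pj * n / rank
                    for rank, pj in enumerate(np.sort(p), start=1)
                    if pj >= p[i] - 1e-15
                ]
                adj[i] = min(1.0, min(candidates))
            return adj

        rng = np.random.default_rng(16)
        for _ in range(200):
            p = rng.random(rng.integers(1, 25))
            np.testing.assert_allclose(de.adjust_bh(p), brute(p), atol=1e-12)


class TestRemoveBatchEffect:
    def test_additive_offset_removed(self):
        rng = np.random.default_rng(17)
        base = rng.normal(20, 1, (30, 8))
        batch_shift = np.array([0.0] * 4 + [3.0] * 4)
        values = base + batch_shift
        ds = make_dataset(values, groups=["A", "B"] * 4,
                          batch=["b1"] * 4 + ["b2"] * 4)
        design = de.build_design(ds.sample_meta, ["group"])
        out = de.remove_batch_effect(ds, design, "batch").intensities.to_numpy()
        means_b1 = out[:, :4].mean(axis=1)
        means_b2 = out[:, 4:].mean(axis=1)
        np.testing.assert_allclose(means_b1, means_b2, atol=1e-8)

    def test_no_batch_effect_little_change(self):
        rng = np.random.default_rng(18)
        values = rng.normal(20, 1, (100, 8))
        ds = make_dataset(values, groups=["A", "B"] * 4,
                          batch=["b1"] * 4 + ["b2"] * 4)
        design = de.build_design(ds.sample_meta, ["group"])
        out = de.remove_batch_effect(ds, design, "batch").intensities.to_numpy()
        # estimated batch terms are pure noise, O(sd/sqrt(n)) per feature
        assert np.abs(out - values).max() < 2.5

    def test_aliased_batch_errors(self):
        ds = make_dataset(np.ones((2, 4)), groups=["A", "A", "B", "B"],
                          batch=["b1", "b1", "b2", "b2"])
        design = de.build_design(ds.sample_meta, ["group"])
        with pytest.raises(InputError, match="aliased"):
            de.remove_batch_effect(ds, design, "batch")

    def test_correction_restores_group_separation(self):
        # batch variance dominates the treatment effect: raw PCA-space
        # silhouette over treatment is poor, corrected silhouette improves
        rng = np.random.default_rng(19)
        n_feat = 200
        groups = ["A", "B"] * 4
        batches = ["b1"] * 4 + ["b2"] * 4
        effect = np.where(np.array(groups) == "B", 0.5, 0.0)
        batch_offsets = rng.normal(0, 4.0, (n_feat, 2))
        batch_idx = np.array([0] * 4 + [1] * 4)
        values = (
            rng.normal(20, 0.3, (n_feat, 8))
            + effect[None, :] * (rng.random((n_feat, 1)) < 0.5)
            + batch_offsets[:, batch_idx]
        )
        ds = make_dataset(values, groups=groups, batch=batches)
        design = de.build_design(ds.sample_meta, ["group"])
        corrected = de.remove_batch_effect(ds, design, "batch")
        sil_raw = pp.avg_silhouette(ds, "group")
        sil_corr = pp.avg_silhouette(corrected, "group")
        assert sil_corr > sil_raw


class TestRankMetric:
    def _result(self, rows):
        table = pd.DataFrame(
            rows, columns=["gene_symbol", "logFC", "P.Value"],
            index=[f"f{i}" for i in range(len(rows))],
        )
        table["s2"] = 1.0
        table["df_resid"] = 4.0
        table["AveExpr"] = 0.0
        table["contrast_var"] = 1.0
        table["adj.P.Val"] = table["P.Value"]
        table["t"] = 0.0
        design = de.DesignMatrix(matrix=pd.DataFrame({"(Intercept)": [1.0]}))
        res = de.DiffExpResult(
            table=table,
            contrast=de.Contrast("c", np.array([1.0])),
            design=design,
            d0=4.0,
            s0_sq=1.0,
        )
        return res

    def test_signed_logp_formula(self):
        res = self._result([("g1", 2.0, 0.01), ("g2", -1.0, 0.1)])
        scores = de.rank_metric(res)
        assert scores["g1"] == pytest.approx(2.0)
        assert scores["g2"] == pytest.approx(-1.0)

    def test_max_magnitude_per_gene(self):
        res = self._result([("g1", 1.2, 10 ** -1.2), ("g1", -3.0, 10 ** -3.0)])
        scores = de.rank_metric(res)
        assert scores["g1"] == pytest.approx(-3.0)


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
def test_bh_is_monotone_and_bounded(pvals):
    adj = de.adjust_bh(pvals)
    p = np.asarray(pvals)
    assert np.all(adj >= p - 1e-12)
    assert np.all(adj <= 1.0 + 1e-12)
    order = np.argsort(p, kind="mergesort")
    assert np.all(np.diff(adj[order]) >= -1e-12)
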