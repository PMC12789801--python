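"""Filtering, normalization menu, imputation and QC metric contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicweave import preprocess as pp
from omicweave.containers import InputError
from omicweave.synth import SyntheticSpec, generate_multiomic

from conftest import make_dataset


class TestFilters:
    def test_flagged_rows_removed(self):
        ds = make_dataset(np.ones((10, 2)))
        ds.feature_meta.loc[["f0", "f5"], "is_contaminant"] = True
        out = pp.filter_flagged(ds)
        assert out.n_features == 8 and "f0" not in out.feature_ids

    def test_no_flags_identity(self):
        ds = make_dataset(np.ones((5, 2)))
        assert pp.filter_flagged(ds).n_features == 5

    def test_all_flagged_errors(self):
        ds = make_dataset(np.ones((2, 2)))
        ds.feature_meta["is_reverse"] = True
        with pytest.raises(InputError):
            pp.filter_flagged(ds)

    @pytest.mark.parametrize(
        "n_missing,threshold,kept",
        [(2, 0.30, False), (0, 0.30, True), (2, 1.0, True)],
    )
    def test_missingness_threshold(self, n_missing, threshold, kept):
        # 6 samples; 2/6 = 0.333 > 0.30 -> removed at the default threshold
        values = np.ones((1, 6))
        values[0, :n_missing] = np.nan
        ds = make_dataset(values)
        out = pp.filter_missing(ds, threshold)
        assert (out.n_features == 1) is kept


class TestLogTransform:
    def test_log2_value(self):
        ds = make_dataset([[8.0, 2.0]], log_transformed=False)
        out = pp.log_transform(ds)
        assert out.intensities.iloc[0, 0] == pytest.approx(3.0)
        assert out.log_transformed

    def test_double_transform_errors(self):
        ds = make_dataset([[1.0]], log_transformed=True)
        with pytest.raises(InputError, match="already"):
            pp.log_transform(ds)

    def test_pseudocount(self):
        ds = make_dataset([[0.0]], log_transformed=False)
        out = pp.log_transform(ds, pseudocount=1.0)
        assert out.intensities.iloc[0, 0] == 0.0

    def test_nonpositive_names_cell(self):
        ds = make_dataset([[4.0], [0.0]], log_transformed=False)
        with pytest.raises(InputError, match="f1"):
            pp.log_transform(ds)


class TestNormalize:
    def test_quantile_rank_means(self):
        ds = make_dataset(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        out = pp.normalize(ds, "quantile").intensities.to_numpy()
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out, expected)

    def test_quantile_identical_column_multisets(self):
        rng = np.random.default_rng(3)
        ds = make_dataset(rng.normal(size=(40, 5)))
        out = pp.normalize(ds, "quantile").intensities.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_median_centers_to_grand_mean(self):
        ds = make_dataset(np.array([[4.0, 6.0], [5.0, 7.0], [6.0, 8.0]]))
        out = pp.normalize(ds, "median").intensities
        np.testing.assert_allclose(np.median(out, axis=0), [6.0, 6.0])

    def test_medianmad_targets(self):
        rng = np.random.default_rng(5)
        ds = make_dataset(rng.normal(0, 1, (51, 4)) * [1, 2, 3, 4] + [0, 5, -3, 2])
        raw = ds.intensities.to_numpy()
        meds = np.median(raw, axis=0)
        mads = np.array([np.median(np.abs(c - m)) for c, m in zip(raw.T, meds)])
        out = pp.normalize(ds, "medianMAD").intensities.to_numpy()
        for j in range(4):
            assert np.median(out[:, j]) == pytest.approx(meds.mean(), abs=1e-9)
            mad_j = np.median(np.abs(out[:, j] - np.median(out[:, j])))
            assert mad_j == pytest.approx(mads.mean(), abs=1e-9)

    def test_ztransform(self):
        ds = make_dataset(np.array([[1.0], [2.0], [3.0]]))
        out = pp.normalize(ds, "ztransform").intensities.to_numpy().ravel()
        np.testing.assert_allclose(out, [-1.0, 0.0, 1.0])

    def test_loess_removes_intensity_dependent_bias(self):
        rng = np.random.default_rng(7)
        base = rng.normal(20, 2, 300)
        col1 = base + rng.normal(0, 0.05, 300)
        # second column with an intensity-dependent distortion
        col2 = base + 0.2 * (base - 20) + rng.normal(0, 0.05, 300)
        ds = make_dataset(np.column_stack([col1, col2]))
        out = pp.normalize(ds, "loess").intensities.to_numpy()
        m_before = col1 - col2
        m_after = out[:, 0] - out[:, 1]
        a = 0.5 * (col1 + col2)
        slope_before = np.polyfit(a, m_before, 1)[0]
        slope_after = np.polyfit(a, m_after, 1)[0]
        assert abs(slope_after) < abs(slope_before) / 4

    def test_irs_aligns_plexes(self):
        rng = np.random.default_rng(11)
        base = rng.normal(20, 1, (30, 1))
        # plex 2 shifted per feature
        shift = rng.normal(2, 0.5, (30, 1))
        values = np.hstack([base + rng.normal(0, .01, (30, 2)),
                            base + shift + rng.normal(0, .01, (30, 2))])
        ds = make_dataset(values, groups=["A", "B", "A", "B"],
                          plex=["p1", "p1", "p2", "p2"])
        out = pp.normalize(ds, "irs").intensities.to_numpy()
        plex_means_1 = out[:, :2].mean(axis=1)
        plex_means_2 = out[:, 2:].mean(axis=1)
        np.testing.assert_allclose(plex_means_1, plex_means_2, atol=1e-2)

    def test_irs_without_plex_errors(self):
        ds = make_dataset(np.ones((3, 2)))
        with pytest.raises(pp.ConfigurationError):
            pp.normalize(ds, "irs")

    def test_missing_preserved_in_place(self):
        values = np.arange(12.0).reshape(4, 3) + 1
        values[1, 2] = np.nan
        ds = make_dataset(values)
        for method in ("quantile", "median", "medianMAD", "ztransform"):
            out = pp.normalize(ds, method).intensities.to_numpy()
            assert np.isnan(out[1, 2]) and np.isnan(out).sum() == 1


class TestImputeLLS:
    def test_rank1_exact_recovery(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        coef = np.array([1.0, 2.0, 0.5, 3.0])
        values = np.outer(coef, v)
        masked = values.copy()
        masked[0, 2] = np.nan
        ds = make_dataset(masked)
        out = pp.impute_lls(ds, k_neighbors=1)
        assert out.intensities.iloc[0, 2] == pytest.approx(values[0, 2], abs=1e-8)

    def test_no_missing_identity(self):
        ds = make_dataset(np.arange(6.0).reshape(2, 3))
        out = pp.impute_lls(ds)
        pd.testing.assert_frame_equal(out.intensities, ds.intensities)

    def test_constant_neighbor_falls_back_to_row_mean(self):
        values = np.array([[1.0, 2.0, np.nan], [5.0, 5.0, 5.0]])
        ds = make_dataset(values)
        out = pp.impute_lls(ds, k_neighbors=1)
        filled = out.intensities.iloc[0, 2]
        assert np.isfinite(filled)

    def test_observed_cells_untouched(self):
        rng = np.random.default_rng(13)
        values = rng.normal(size=(20, 6))
        mask = rng.random((20, 6)) < 0.1
        mask[:, 0] = False  # keep one complete column
        masked = np.where(mask, np.nan, values)
        ds = make_dataset(masked)
        out = pp.impute_lls(ds).intensities.to_numpy()
        np.testing.assert_array_equal(out[~mask], masked[~mask])
        assert not np.isnan(out).any()

    def test_bad_k_errors(self):
        ds = make_dataset(np.ones((2, 2)))
        with pytest.raises(pp.ConfigurationError):
            pp.impute_lls(ds, k_neighbors=0)


class TestQcMetrics:
    def test_two_point_formulas(self):
        ds = make_dataset([[1.0, 3.0]], groups=["A", "A"])
        m = pp.qc_metrics(ds)
        assert m["PMAD"] == pytest.approx(1.0)
        assert m["PEV"] == pytest.approx(2.0)
        # replicates [2,4]: sd/mean = sqrt(2)/3
        m2 = pp.qc_metrics(make_dataset([[2.0, 4.0]], groups=["A", "A"]))
        assert m2["PCV"] == pytest.approx(np.sqrt(2) / 3, abs=1e-4)

    def test_identical_replicates_zero(self):
        ds = make_dataset([[5.0, 5.0, 5.0]], groups=["A"] * 3)
        m = pp.qc_metrics(ds)
        assert m["PMAD"] == m["PCV"] == m["PEV"] == 0.0

    def test_reordering_invariance(self):
        rng = np.random.default_rng(21)
        values = rng.normal(20, 1, (10, 6))
        groups = ["A", "A", "A", "B", "B", "B"]
        ds = make_dataset(values, groups=groups)
        m1 = pp.qc_metrics(ds)
        perm_feat = rng.permutation(10)
        # swap replicates within groups
        perm_samp = [1, 2, 0, 5, 3, 4]
        ds2 = make_dataset(values[perm_feat][:, perm_samp],
                           groups=[groups[j] for j in perm_samp])
        m2 = pp.qc_metrics(ds2)
        for key in m1:
            assert m1[key] == pytest.approx(m2[key])

    def test_no_replicated_group_errors(self):
        ds = make_dataset(np.ones((2, 2)), groups=["A", "B"])
        with pytest.raises(InputError):
            pp.qc_metrics(ds)


class TestSilhouette:
    def test_hand_computed_1d(self):
        # A = {0, 1}, B = {10, 11}: ASW ~= 0.8997
        ds = make_dataset([[0.0, 1.0, 10.0, 11.0]], groups=["A", "A", "B", "B"])
        asw = pp.avg_silhouette(ds, space="features")
        expected = (0.90476 + 0.89474 + 0.90476 + 0.89474) / 4
        assert asw == pytest.approx(expected, abs=1e-4)

    def test_identical_groups_not_positive(self):
        ds = make_dataset([[1.0, 1.0, 1.0, 1.0]], groups=["A", "A", "B", "B"])
        assert pp.avg_silhouette(ds, space="features") <= 0.0

    def test_large_separation_approaches_one(self):
        ds = make_dataset([[0.0, 0.001, 1e6, 1e6 + 0.001]], groups=["A", "A", "B", "B"])
        assert pp.avg_silhouette(ds, space="features") > 0.999

    def test_single_group_errors(self):
        ds = make_dataset(np.ones((2, 3)), groups=["A", "A", "A"])
        with pytest.raises(InputError):
            pp.avg_silhouette(ds)

    def test_matches_sklearn_on_generic_data(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(2)
        values = np.vstack([rng.normal(0, 1, (4, 5)), rng.normal(3, 1, (4, 5))]).T
        groups = ["A"] * 4 + ["B"] * 4
        ds = make_dataset(values, groups=groups)
        ours = pp.avg_silhouette(ds, space="features")
        theirs = silhouette_score(values.T, groups)
        assert ours == pytest.approx(theirs, abs=1e-10)


class TestEvaluateNormalizations:
    def test_dominating_method_recommended(self):
        rng = np.random.default_rng(17)
        base = rng.normal(20, 1, (60, 6))
        shifts = np.array([0.0, 2.0, -1.5, 1.0, -0.5, 2.5])
        ds = make_dataset(base + shifts, groups=["A"] * 3 + ["B"] * 3)
        report = pp.evaluate_normalizations(ds, ["median", "ztransform"])
        assert report.recommended in ("median", "ztransform")
        assert int(report.table["recommended"].sum()) == 1

    def test_single_method_errors(self):
        ds = make_dataset(np.ones((3, 2)))
        with pytest.raises(pp.ConfigurationError):
            pp.evaluate_normalizations(ds, ["median"])

    def test_median_beats_noop_under_sample_shifts(self):
        # additive per-sample shifts only: median centring should restore
        # the no-shift PMAD while the raw data stays inflated
        rng = np.random.default_rng(29)
        clean = rng.normal(20, 0.1, (200, 6))
        shifts = rng.normal(0, 1.5, 6)
        ds_shifted = make_dataset(clean + shifts, groups=["A"] * 3 + ["B"] * 3)
        ds_clean = make_dataset(clean, groups=["A"] * 3 + ["B"] * 3)
        pmad_shifted = pp.qc_metrics(ds_shifted)["PMAD"]
        pmad_norm = pp.qc_metrics(pp.normalize(ds_shifted, "median"))["PMAD"]
        pmad_clean = pp.qc_metrics(ds_clean)["PMAD"]
        assert pmad_norm < pmad_shifted
        assert pmad_norm == pytest.approx(pmad_clean, rel=0.15)


class TestVariableFeaturesAndPca:
    def test_top_fraction_count(self):
        rng = np.random.default_rng(31)
        ds = make_dataset(rng.normal(size=(100, 5)))
        assert len(pp.variable_features(ds, 0.10)) == 10
        assert len(pp.variable_features(ds, 1.0)) == 100

    def test_constant_feature_never_selected(self):
        rng = np.random.default_rng(33)
        values = rng.normal(size=(10, 4))
        values[3] = 7.0
        ds = make_dataset(values)
        assert "f3" not in pp.variable_features(ds, 0.5)

    def test_pca_line_explains_everything(self):
        t = np.linspace(0, 1, 6)
        values = np.vstack([2 * t, -3 * t])  # 2 features on a line
        ds = make_dataset(values)
        _, _, var_frac = pp.pca_scores(ds, 2)
        assert var_frac[0] == pytest.approx(1.0)

    def test_pca_scores_orthogonal(self):
        rng = np.random.default_rng(37)
        ds = make_dataset(rng.normal(size=(30, 8)))
        scores, _, var_frac = pp.pca_scores(ds, 3)
        s = scores.to_numpy()
        assert abs(s[:, 0] @ s[:, 1]) < 1e-8
        assert np.all(np.diff(var_frac) <= 1e-12) and var_frac.sum() <= 1 + 1e-9

    def test_too_many_components_errors(self):
        ds = make_dataset(np.ones((3, 2)))
        with pytest.raises(pp.ConfigurationError):
            pp.pca_scores(ds, 5)


class TestMdTable:
    def test_aligned_to_fit_result(self):
        from omicweave import diffexp as de

        rng = np.random.default_rng(41)
        values = rng.normal(20, 1, (8, 4))
        ds = make_dataset(values, groups=["A", "A", "B", "B"])
        design = de.build_design(ds.sample_meta, ["group"])
        fit = de.fit_linear_model(ds, design, "groupB")
        table = pp.md_table(fit)
        assert list(table.index) == list(ds.feature_ids)
        np.testing.assert_allclose(table["AveExpr"].to_numpy(), values.mean(axis=1))
        np.testing.assert_allclose(
            table["logFC"].to_numpy(), fit.table["logFC"].to_numpy()
        )


@st.composite
def tie_free_matrices(draw):
    n = draw(st.integers(3, 12))
    p = draw(st.integers(2, 5))
    cols = [
        draw(st.lists(st.floats(-50, 50, allow_nan=False), min_size=n, max_size=n, unique=True))
        for _ in range(p)
    ]
    return np.asarray(cols, float).T


@settings(deadline=None, max_examples=25)
@given(tie_free_matrices())
def test_quantile_columns_share_sorted_values(values):
    # exact multiset identity holds for tie-free complete columns
    ds = make_dataset(values)
    out = pp.normalize(ds, "quantile").intensities.to_numpy()
    for j in range(1, out.shape[1]):
        np.testing.assert_allclose(np.sort(out[:, j]), np.sort(out[:, 0]), atol=1e-9)
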