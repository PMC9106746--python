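"""Proteome normalization, replicate-support filtering, imputation rules,
and Dunnett many-to-one testing."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from heatomics._stats import dunnett_adjusted_pvalues
from heatomics.design import TimeCourseDesign, default_design
from heatomics.matrices import ProteomeMatrix
from heatomics.proteome import (
    dunnett_test,
    filter_replicate_support,
    impute,
    normalize_median_of_ratios,
)


def _design_2groups(n_rep=3):
    return default_design(treatments=("heat35",), heat_times=(0.0,), recovery_times=(), n_replicates=n_rep)


def _matrix(data, columns, proteotypic=None):
    df = pd.DataFrame(data).T
    df.columns = columns
    proteo = None
    if proteotypic is not None:
        proteo = pd.Series(proteotypic)
    return ProteomeMatrix(df.astype(float), proteo)


class TestMedianOfRatios:
    def test_hand_example(self):
        m = _matrix({"p1": [2, 8], "p2": [3, 12]}, ["s1", "s2"])
        norm, factors = normalize_median_of_ratios(m)
        assert factors.tolist() == pytest.approx([0.5, 2.0])
        assert norm.intensities.loc["p1"].tolist() == pytest.approx([4.0, 4.0])
        assert norm.intensities.loc["p2"].tolist() == pytest.approx([6.0, 6.0])

    def test_idempotent_on_normalized_matrix(self):
        m = _matrix({"p1": [2, 8], "p2": [3, 12]}, ["s1", "s2"])
        norm, _ = normalize_median_of_ratios(m)
        again, factors = normalize_median_of_ratios(norm)
        assert np.allclose(factors, 1.0)
        pd.testing.assert_frame_equal(norm.intensities, again.intensities)

    def test_column_scaling_invariance_up_to_global_constant(self):
        # scaling one column by 10 moves its factor x10 relative to the
        # others and leaves the normalized matrix unchanged up to a single
        # global constant (the rescaled geometric-mean reference)
        m = _matrix({"p1": [2, 8], "p2": [3, 12]}, ["s1", "s2"])
        scaled = _matrix({"p1": [2, 80], "p2": [3, 120]}, ["s1", "s2"])
        norm_a, fa = normalize_median_of_ratios(m)
        norm_b, fb = normalize_median_of_ratios(scaled)
        assert (fb["s2"] / fb["s1"]) == pytest.approx(10 * fa["s2"] / fa["s1"])
        ratio = norm_b.intensities / norm_a.intensities
        assert np.allclose(ratio.to_numpy(), ratio.iloc[0, 0])

    def test_rank_order_within_sample_preserved(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.lognormal(3, 1, (30, 4)), columns=list("abcd"),
            index=[f"p{i}" for i in range(30)],
        )
        norm, _ = normalize_median_of_ratios(ProteomeMatrix(df))
        for c in df.columns:
            assert (df[c].rank() == norm.intensities[c].rank()).all()

    def test_no_complete_rows_errors(self):
        df = pd.DataFrame({"s1": [1.0, np.nan], "s2": [np.nan, 2.0]}, index=["p1", "p2"])
        with pytest.raises(ValueError, match="filter"):
            normalize_median_of_ratios(ProteomeMatrix(df))


class TestReplicateSupport:
    def test_rule_applications(self):
        design = _design_2groups()
        cols = design.sample_ids  # 3 pre_heat + 3 heat
        twice_one_group = [1.0, 2.0, np.nan, np.nan, np.nan, np.nan]
        once_per_group = [1.0, np.nan, np.nan, 2.0, np.nan, np.nan]
        full = [1.0] * 6
        m = _matrix(
            {"kept": twice_one_group, "dropped": once_per_group, "full": full}, cols
        )
        out = filter_replicate_support(m, design)
        assert sorted(out.protein_ids) == ["full", "kept"]


class TestImpute:
    def test_partial_group_zero_sd_gives_group_mean(self):
        design = _design_2groups()
        cols = design.sample_ids
        m = _matrix({"p1": [4.0, 16.0, np.nan, 2.0, 2.0, 2.0]}, cols)
        out, report = impute(m, design, global_sd=0.0, seed=0)
        # log2 mean of (4, 16) = 3 -> 8.0
        assert out.intensities.loc["p1", cols[2]] == pytest.approx(8.0)
        assert report.status.loc["p1", ("heat35", "pre_heat", 0.0)] == "partial_imputed"
        assert report.status.loc["p1", ("heat35", "heat", 0.0)] == "observed"

    def test_forced_1nn_duplicate_donor(self):
        design = _design_2groups()
        cols = design.sample_ids
        donor = [4.0, 4.0, 4.0, 32.0, 32.0, 32.0]
        query = [4.0, 4.0, 4.0, np.nan, np.nan, np.nan]
        other = [1000.0, 1000.0, 1000.0, 1.0, 1.0, 1.0]
        m = _matrix({"donor": donor, "query": query, "other": other}, cols)
        out, report = impute(m, design, k=1, global_sd=0.0, seed=0)
        assert np.allclose(out.intensities.loc["query", cols[3:]], 32.0)
        key = ("heat35", "heat", 0.0)
        assert report.neighbors[("query", key)] == ["donor"]
        assert report.status.loc["query", key] == "knn_imputed"

    def test_rule_three_left_missing(self):
        # empty group whose only adjacent group is also empty stays missing
        design = default_design(
            treatments=("heat35",), heat_times=(0.0, 1.0), recovery_times=(), n_replicates=2
        )
        cols = design.sample_ids  # pre(2) heat0(2) heat1(2)
        m = _matrix({"p1": [4.0, 4.0, np.nan, np.nan, np.nan, np.nan],
                     "p2": [4.0] * 6}, cols)
        out, report = impute(m, design, global_sd=0.0, seed=0)
        key_h1 = ("heat35", "heat", 1.0)
        assert report.status.loc["p1", key_h1] == "left_missing"
        assert out.intensities.loc["p1", cols[4:]].isna().all()
        # heat 0 h is adjacent to the observed pre-heat group -> imputed
        key_h0 = ("heat35", "heat", 0.0)
        assert report.status.loc["p1", key_h0] == "knn_imputed"

    def test_observed_cells_never_altered_and_all_missing_accounted(self, heat35_design, small_omics):
        _, protm, _, _ = small_omics
        filtered = filter_replicate_support(protm, heat35_design)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            norm, _ = normalize_median_of_ratios(filtered)
            out, report = impute(norm, heat35_design, seed=1)
        obs = ~norm.intensities.isna()
        pd.testing.assert_frame_equal(
            out.intensities.where(obs), norm.intensities.where(obs)
        )
        # every originally-missing cell is either imputed or left missing
        still_missing = out.intensities.isna()
        assert ((~obs) == (out.imputed_mask | still_missing)).all().all()

    def test_masked_group_recovery_bias(self, heat35_design):
        """Monte-Carlo: masking whole groups then imputing recovers the
        truth with < 0.2 log2 units average (signed) bias."""
        from heatomics.simulate import SimRecipe, simulate_omics

        errs = []
        for seed in range(6):
            rec = SimRecipe(seed=seed, n_genes=300, n_proteins=120,
                            mcar_rate=0.0, mnar_scale=0.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, protm, _, truth = simulate_omics(rec, heat35_design)
            vals = protm.intensities.copy()
            rng = np.random.default_rng(seed)
            keys = heat35_design.group_keys()
            masked = []
            for prot in vals.index[:40]:
                key = keys[rng.integers(1, len(keys))]
                cols = heat35_design.samples_for(*key)
                truth_vals = np.log2(vals.loc[prot, cols].astype(float))
                vals.loc[prot, cols] = np.nan
                masked.append((prot, cols, truth_vals.mean()))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out, _ = impute(ProteomeMatrix(vals), heat35_design, seed=seed)
            for prot, cols, true_mean in masked:
                got = np.log2(out.intensities.loc[prot, cols].astype(float))
                if got.notna().any():
                    errs.append(got.mean() - true_mean)
        assert abs(np.mean(errs)) < 0.2  # no systematic bias
        assert np.mean(np.abs(errs)) < 0.5  # scatter at the noise scale


class TestDunnett:
    def test_two_groups_reduces_to_student_t(self):
        design = _design_2groups()
        cols = design.sample_ids
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            np.exp2(rng.normal(10, 0.5, (20, 6))), columns=cols,
            index=[f"p{i}" for i in range(20)],
        )
        table = dunnett_test(ProteomeMatrix(df), design, "heat35")
        for _, row in table.iterrows():
            x = np.log2(df.loc[row["protein_id"], cols[:3]].astype(float))
            y = np.log2(df.loc[row["protein_id"], cols[3:]].astype(float))
            t, p = stats.ttest_ind(y, x, equal_var=True)
            assert row["p_adj"] == pytest.approx(p, abs=2e-3)

    def test_adjusted_never_below_raw(self, heat35_design, small_omics):
        _, protm, _, _ = small_omics
        full = protm.intensities.dropna()
        table = dunnett_test(
            ProteomeMatrix(full), heat35_design, "heat35", exclude_imputed=False
        )
        assert (table["p_adj"] >= table["p_raw"] - 1e-9).all()

    def test_matches_scipy_dunnett(self):
        rng = np.random.default_rng(8)
        ctrl = rng.normal(0, 1, 4)
        groups = [rng.normal(0.8, 1, 4) for _ in range(5)]
        res = stats.dunnett(*groups, control=ctrl)
        ours = dunnett_adjusted_pvalues(res.statistic, 5, 6 * 4 - 6)
        assert np.allclose(ours, res.pvalue, atol=5e-3)

    def test_planted_shift_detected(self):
        design = default_design(
            treatments=("heat35",), heat_times=(0.0, 1.0, 2.0), recovery_times=()
        )
        cols = design.sample_ids
        rng = np.random.default_rng(5)
        log2 = rng.normal(10, 0.3, (50, len(cols)))
        heat2 = [i for i, s in enumerate(cols) if "heat_2h" in s]
        log2[0, heat2] += 2.0  # +2 log2 shift at one time point
        df = pd.DataFrame(np.exp2(log2), columns=cols, index=[f"p{i}" for i in range(50)])
        table = dunnett_test(ProteomeMatrix(df), design, "heat35")
        hit = table[(table["protein_id"] == "p0") & (table["time_h"] == 2.0)]
        assert (hit["p_adj"] < 0.05).all()

    def test_control_replicate_requirement(self):
        design = _design_2groups(n_rep=1)
        df = pd.DataFrame(
            {s: [2.0] for s in design.sample_ids}, index=["p1"]
        )
        with pytest.raises(ValueError, match="control"):
            dunnett_test(ProteomeMatrix(df), design, "heat35")
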