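"""Count filtering, TPM, the three-criterion DE call, DEG set algebra,
and the SVD decomposition of log expression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heatomics._stats import bh_adjust
from heatomics.design import default_design
from heatomics.matrices import ExpressionMatrix
from heatomics.simulate import SimRecipe, simulate_omics
from heatomics.transcriptome import (
    compute_tpm,
    deg_sets,
    differential_expression,
    filter_genes,
    nb_wald_two_group,
    surprisal_analysis,
)


def _expr(counts: dict, lengths=None, samples=None):
    df = pd.DataFrame(counts).T
    if samples is not None:
        df.columns = samples
    lengths = pd.Series(
        lengths if lengths is not None else {g: 1000.0 for g in df.index}
    )
    return ExpressionMatrix(df.astype(np.int64), lengths)


class TestFilterGenes:
    def test_boundary_one_of_ten_samples(self):
        # ceil(0.10 * 10) = 1: a single sample with exactly 10 reads keeps the gene
        counts = {"g1": [10] + [0] * 9, "g2": [9] * 10}
        m = filter_genes(_expr(counts))
        assert m.gene_ids == ["g1"]

    def test_five_gene_toy_three_survive(self):
        counts = {
            "all9": [9] * 10,  # never reaches 10 -> dropped
            "one10": [10] + [0] * 9,  # 10 in 1 of 10 (=10%) -> kept
            "ten_pct": [10] + [0] * 9,  # same boundary -> kept
            "zeros": [0] * 10,  # dropped
            "high": [500] * 10,  # kept
        }
        m = filter_genes(_expr(counts))
        assert sorted(m.gene_ids) == ["high", "one10", "ten_pct"]

    def test_empty_result_warns_not_errors(self):
        with pytest.warns(UserWarning, match="every gene"):
            m = filter_genes(_expr({"g": [0, 0]}))
        assert m.gene_ids == []


class TestTpm:
    def test_single_gene_forced_to_1e6(self):
        m = _expr({"g": [7, 3]})
        tpm = compute_tpm(m).tpm
        assert np.allclose(tpm.to_numpy(), 1e6)

    def test_hand_arithmetic(self):
        m = _expr({"g1": [10], "g2": [30]}, lengths={"g1": 1000.0, "g2": 2000.0})
        tpm = compute_tpm(m).tpm
        assert tpm.loc["g1"].iloc[0] == pytest.approx(4e5)
        assert tpm.loc["g2"].iloc[0] == pytest.approx(6e5)

    def test_columns_sum_to_1e6(self, small_omics):
        expr = small_omics[0]
        tpm = compute_tpm(expr).tpm
        assert np.allclose(tpm.sum(axis=0), 1e6, atol=1e-6 * 1e6 * 1e-6 + 1e-3)

    def test_zero_column_errors(self):
        m = _expr({"g": [0, 5]}, samples=["dead", "ok"])
        with pytest.raises(ValueError, match="dead"):
            compute_tpm(m)


class TestNbModel:
    def test_matches_statsmodels_glm(self):
        """Dual route: the vectorised IRLS against statsmodels' scalar GLM
        at the same fixed dispersion."""
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        x = np.array([0, 0, 0, 1, 1, 1])
        y = rng.negative_binomial(10, 10 / (10 + 150), (5, 6)).astype(float)
        offset = np.log(np.full(6, 1.0))
        b1, se1, _, phi = nb_wald_two_group(y, offset, x)
        X = sm.add_constant(x.astype(float))
        for i in range(5):
            fit = sm.GLM(
                y[i], X, family=sm.families.NegativeBinomial(alpha=float(phi[i]))
            ).fit()
            assert b1[i] == pytest.approx(fit.params[1], rel=1e-6)
            assert se1[i] == pytest.approx(fit.bse[1], rel=1e-5)

    def test_planted_fourfold_gene_is_significant(self):
        design = default_design(treatments=("heat35",), heat_times=(0.0,), recovery_times=())
        rng = np.random.default_rng(7)
        n_genes = 300
        mu = np.full((n_genes, 6), 100.0)
        mu[0, 3:] = 400.0  # planted 4-fold gene
        phi = 0.05
        y = rng.negative_binomial(1 / phi, (1 / phi) / (1 / phi + mu))
        counts = pd.DataFrame(y, index=[f"g{i}" for i in range(n_genes)],
                              columns=design.sample_ids)
        m = ExpressionMatrix(counts, pd.Series(1000.0, index=counts.index))
        table = differential_expression(m, design, treatments=("heat35",))
        assert bool(table[table["gene_id"] == "g0"]["significant"].iloc[0])

    def test_third_criterion_blocks_low_abundance_calls(self):
        """A gene with large, certain fold-change but TPM means differing by
        < 1 must not be flagged."""
        design = default_design(treatments=("heat35",), heat_times=(0.0,), recovery_times=())
        rng = np.random.default_rng(3)
        n_genes = 200
        mu = np.full((n_genes, 6), 2000.0)
        mu[0] = [2000, 2000, 2000, 8000, 8000, 8000]  # 4-fold, precise counts
        y = rng.negative_binomial(100, 100 / (100 + mu))
        counts = pd.DataFrame(y, index=[f"g{i}" for i in range(n_genes)],
                              columns=design.sample_ids)
        lengths = pd.Series(1000.0, index=counts.index)
        lengths["g0"] = 2.5e7  # huge gene: big counts but TPM well below 1
        m = ExpressionMatrix(counts, lengths)
        table = differential_expression(m, design, treatments=("heat35",))
        row = table[table["gene_id"] == "g0"].iloc[0]
        assert abs(row["log2fc"]) > 1 and row["fdr"] < 0.05
        assert abs(row["tpm_ctrl"] - row["tpm_trt"]) < 1
        assert not row["significant"]

    def test_flag_invariant_to_gene_and_sample_order(self):
        from heatomics.simulate import Archetype

        design = default_design(treatments=("heat35",), heat_times=(0.0, 0.5), recovery_times=())
        arch = Archetype(
            "burst", 30, {("heat35", "heat", 0.0): 2.0, ("heat35", "heat", 0.5): 1.5}
        )
        rec = SimRecipe(seed=5, n_genes=300, n_proteins=10, archetypes=(arch,))
        expr, *_ = simulate_omics(rec, design)
        base = differential_expression(expr, design, treatments=("heat35",))
        perm_genes = expr.counts.sample(frac=1.0, random_state=0)
        perm = ExpressionMatrix(
            perm_genes[list(np.random.default_rng(1).permutation(expr.sample_ids))],
            expr.gene_length_bp,
        )
        other = differential_expression(perm, design, treatments=("heat35",))
        a = base.set_index(["gene_id", "phase", "time_h"])["significant"]
        b = other.set_index(["gene_id", "phase", "time_h"])["significant"]
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_control_only_design_yields_empty_table(self):
        design = default_design(treatments=("ctrl25",))
        rec = SimRecipe(seed=1, n_genes=50, n_proteins=10, archetypes=())
        expr, *_ = simulate_omics(rec, design)
        table = differential_expression(expr, design, treatments=())
        assert len(table) == 0


class TestDegSets:
    def _table(self, up, down=()):
        rows = []
        for g in up:
            rows.append((g, "heat", 1.0, 2.0, True))
        for g in down:
            rows.append((g, "heat", 1.0, -2.0, True))
        return pd.DataFrame(
            rows, columns=["gene_id", "phase", "time_h", "log2fc", "significant"]
        )

    def test_toy_enumeration(self):
        a = self._table(["a", "b", "c"])
        b = self._table(["b", "c", "d", "e"])
        out = deg_sets(a, b)
        row = out[(out["direction"] == "up")].iloc[0]
        assert (row["overlap"], row["unique_a"], row["unique_b"]) == (2, 1, 2)

    def test_identical_and_disjoint(self):
        a = self._table(["x", "y"])
        same = deg_sets(a, a)
        up = same[same["direction"] == "up"].iloc[0]
        assert up["unique_a"] == 0 and up["unique_b"] == 0 and up["overlap"] == 2
        b = self._table(["z"])
        disj = deg_sets(a, b)
        up = disj[disj["direction"] == "up"].iloc[0]
        assert up["overlap"] == 0


class TestSurprisal:
    def _tpm_frame(self, mat, n_t):
        return pd.DataFrame(
            mat, index=[f"g{i}" for i in range(mat.shape[0])],
            columns=[f"t{j}" for j in range(n_t)],
        )

    def test_rank_one_matrix_is_all_baseline(self):
        rng = np.random.default_rng(0)
        g = np.exp(rng.normal(3, 1, 50))
        mat = np.outer(g, np.ones(6)) * 100
        dec = surprisal_analysis(self._tpm_frame(mat, 6))
        assert dec.variance_fraction[0] > 0.999
        lam1 = dec.potentials.iloc[1].to_numpy()
        assert np.linalg.norm(lam1) / np.linalg.norm(dec.potentials.iloc[0]) < 0.05

    def test_planted_orthogonal_patterns_recovered(self):
        rng = np.random.default_rng(2)
        n_t = 8
        q, _ = np.linalg.qr(rng.standard_normal((n_t, 4)))
        patterns = q.T[1:4]  # 3 orthogonal, mean-free-ish patterns
        weights = rng.standard_normal((300, 3)) * [3, 2, 1]
        base = rng.normal(5, 1, 300)
        ln = base[:, None] + weights @ patterns + 0.01 * rng.standard_normal((300, n_t))
        mat = np.exp(ln) - 1
        mat[mat < 0] = 0
        dec = surprisal_analysis(self._tpm_frame(mat, n_t))
        post = dec.variance_fraction[1:4].sum()
        total_post = 1.0 - dec.variance_fraction[0]
        assert post / total_post >= 0.95

    def test_reconstruction_error_non_increasing_in_k(self, small_omics):
        expr, *_ = small_omics
        tpm = compute_tpm(expr)
        design = default_design(treatments=("heat35",))
        dec = surprisal_analysis(tpm, design, treatment="heat35")
        ln = None
        errs = []
        mat = None
        # reconstruction error vs the replicate-averaged ln matrix
        cols = {}
        for tr, ph, t in design.group_keys("heat35"):
            samples = tpm.tpm.columns.intersection(design.samples_for(tr, ph, t))
            cols[f"{tr}:{ph}:{t:g}"] = tpm.tpm[samples].mean(axis=1)
        target = np.log(pd.DataFrame(cols).to_numpy() + 1)
        for k in range(0, dec.n_retained + 1):
            errs.append(np.linalg.norm(target - dec.reconstruction(k)))
        assert all(e2 <= e1 + 1e-9 for e1, e2 in zip(errs, errs[1:]))

    def test_too_few_time_points_rejected(self):
        mat = np.abs(np.random.default_rng(0).normal(5, 1, (10, 3)))
        with pytest.raises(ValueError, match="4 time points"):
            surprisal_analysis(self._tpm_frame(mat, 3))


class TestBh:
    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=40),
    )
    def test_matches_brute_force(self, pvals):
        """Oracle: q_i = min over j >= rank(i) of p_(j) * m / j."""
        p = np.array(pvals)
        m = p.size
        order = np.argsort(p, kind="mergesort")
        brute = np.empty(m)
        sorted_p = p[order]
        for i in range(m):
            brute[order[i]] = min(
                min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0
            )
        assert np.allclose(bh_adjust(p), brute, atol=1e-12)
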