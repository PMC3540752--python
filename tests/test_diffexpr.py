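import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from biasnet.diffexpr import (
    DEFAULT_FDR_CUTOFF,
    bh_fdr,
    classify_bias,
    log_fold_change,
    moderated_welch,
)

from .conftest import expression_from_log2


def _bh_oracle(p):
    """Literal step-up formula: fdr_i = min_{p_j >= p_i} m * p_j / rank_j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestBhFdr:
    def test_single_and_degenerate_vectors(self):
        assert bh_fdr([0.05]) == pytest.approx([0.05])
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_hand_step_up_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_validation(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(bh_fdr(p), _bh_oracle(p), atol=1e-12)

    @given(seed=st.integers(0, 200), n=st.integers(2, 50))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_monotone_in_p_ordering(self, seed, n):
        p = np.random.default_rng(seed).random(n)
        fdr = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()
        assert (fdr >= p - 1e-12).all()


class TestModeratedWelch:
    def _toy(self, seed=0, n_genes=50, n=3):
        rng = np.random.default_rng(seed)
        log2 = rng.normal(8, 1, size=(n_genes, 2 * n))
        return expression_from_log2(log2, [f"g{i}" for i in range(n_genes)], n, n)

    def test_identical_constant_groups_give_null_result(self):
        log2 = np.tile([[5.0] * 6], (4, 1))
        log2[1:] += np.arange(3)[:, None]  # distinct genes, still flat in sex
        em = expression_from_log2(log2, list("abcd"), 3, 3)
        de = moderated_welch(em, ("gonad", "adult"), d0=0.0)
        assert de.table["t"].to_numpy() == pytest.approx(0.0)
        assert de.table["p"].to_numpy() == pytest.approx(1.0)

    def test_d0_zero_reproduces_classical_welch(self):
        em = self._toy(seed=1)
        de = moderated_welch(em, ("gonad", "adult"), d0=0.0)
        lv = np.log2(np.maximum(em.values.to_numpy(), 1.0))
        t_ref, p_ref = stats.ttest_ind(lv[:, :3], lv[:, 3:], axis=1, equal_var=False)
        assert np.abs(de.table["t"].to_numpy() - t_ref).max() < 1e-10
        assert np.abs(de.table["p"].to_numpy() - p_ref).max() < 1e-10
        # Satterthwaite df closed form
        vm = lv[:, :3].var(axis=1, ddof=1) / 3
        vf = lv[:, 3:].var(axis=1, ddof=1) / 3
        df_ref = (vm + vf) ** 2 / (vm**2 / 2 + vf**2 / 2)
        assert np.abs(de.table["df"].to_numpy() - df_ref).max() < 1e-10

    def test_d0_infinite_gives_fully_pooled_statistic(self):
        em = self._toy(seed=2)
        de = moderated_welch(em, ("gonad", "adult"), d0=np.inf)
        lv = np.log2(np.maximum(em.values.to_numpy(), 1.0))
        s0m = lv[:, :3].var(axis=1, ddof=1).mean()
        s0f = lv[:, 3:].var(axis=1, ddof=1).mean()
        t_ref = (lv[:, :3].mean(axis=1) - lv[:, 3:].mean(axis=1)) / np.sqrt(
            s0m / 3 + s0f / 3
        )
        assert np.abs(de.table["t"].to_numpy() - t_ref).max() < 1e-10
        assert np.isinf(de.table["df"]).all()

    def test_swapping_sex_labels_flips_all_signs(self):
        em = self._toy(seed=3)
        de = moderated_welch(em, ("gonad", "adult"))
        flipped_meta = em.sample_meta.copy()
        flipped_meta["sex"] = flipped_meta["sex"].map(
            {"male": "female", "female": "male"}
        )
        em_flipped = type(em)(values=em.values, sample_meta=flipped_meta)
        de2 = moderated_welch(em_flipped, ("gonad", "adult"))
        assert de2.table["t"].to_numpy() == pytest.approx(
            -de.table["t"].to_numpy()
        )
        assert de2.table["log2fc"].to_numpy() == pytest.approx(
            -de.table["log2fc"].to_numpy()
        )

    def test_missing_sex_in_condition_errors(self):
        em = self._toy()
        meta = em.sample_meta.copy()
        meta["sex"] = "male"
        with pytest.raises(ValueError, match="female"):
            moderated_welch(type(em)(values=em.values, sample_meta=meta), ("gonad", "adult"))

    def test_null_pvalues_approximately_uniform(self):
        """At delta = 0 and 2000 genes the moderated-test p-values are
        close to uniform (KS below 0.05)."""
        from biasnet.synthetic_data import SimParams, simulate_expression, simulate_network

        params = SimParams(seed=5, effect_size_delta=0.0)
        _, truth = simulate_network(params)
        expr = simulate_expression(params, truth)
        de = moderated_welch(expr, ("gonad", "adult"))
        ks = stats.kstest(de.table["p"], "uniform").statistic
        assert ks < 0.05

    def test_power_at_delta_two_log2_units(self):
        """At the default variance scale, a 2-log2-unit sex effect on 20% of
        genes is recovered for >= 80% of affected genes at FDR < 0.1."""
        from biasnet.synthetic_data import SimParams, simulate_expression, simulate_network

        params = SimParams(seed=6, effect_size_delta=2.0)
        _, truth = simulate_network(params)
        expr = simulate_expression(params, truth)
        bias = classify_bias(moderated_welch(expr, ("gonad", "adult")))
        affected = [g for g, l in truth.bias.items() if l != "unbiased"]
        hit = sum(1 for g in affected if bias.labels[g] == truth.bias[g])
        assert hit / len(affected) >= 0.8


class TestClassifyBias:
    def test_default_cutoff(self):
        assert DEFAULT_FDR_CUTOFF == 0.1

    def test_threshold_semantics(self):
        table = pd.DataFrame(
            {
                "t": [2.0, 2.0, -2.0, 0.0],
                "df": [4.0] * 4,
                "p": [0.01, 0.02, 0.01, 0.9],
                "fdr": [0.09, 0.11, 0.05, 0.95],
                "log2fc": [1.2, 3.0, -0.8, 0.0],
                "direction": ["male", "male", "female", "none"],
            },
            index=pd.Index(["a", "b", "c", "d"], name="gene_id"),
        )
        de = type("DE", (), {})()
        from biasnet.diffexpr import DEResult

        de = DEResult(table=table, condition=("gonad", "adult"), d0=1.0, n_male=3, n_female=3)
        bias = classify_bias(de, fdr_cutoff=0.1)
        assert bias.labels["a"] == "male"
        assert bias.labels["b"] == "unbiased"  # fdr 0.11 >= cutoff
        assert bias.labels["c"] == "female"
        assert bias.labels["d"] == "unbiased"
        assert bias.counts() == {"male": 1, "female": 1, "unbiased": 2}

    def test_zero_fold_change_significant_gene_warned_unbiased(self, caplog):
        from biasnet.diffexpr import DEResult

        table = pd.DataFrame(
            {
                "t": [0.0],
                "df": [4.0],
                "p": [0.001],
                "fdr": [0.001],
                "log2fc": [0.0],
                "direction": ["none"],
            },
            index=pd.Index(["a"], name="gene_id"),
        )
        de = DEResult(table=table, condition=("gonad", "adult"), d0=1.0, n_male=3, n_female=3)
        with caplog.at_level("WARNING"):
            bias = classify_bias(de)
        assert bias.labels["a"] == "unbiased"
        assert "zero fold change" in caplog.text

    def test_null_matrix_yields_few_calls(self):
        from biasnet.synthetic_data import SimParams, simulate_expression, simulate_network

        params = SimParams(seed=8, effect_size_delta=0.0)
        _, truth = simulate_network(params)
        expr = simulate_expression(params, truth)
        bias = classify_bias(moderated_welch(expr, ("gonad", "adult")))
        counts = bias.counts()
        assert counts["male"] + counts["female"] <= 10


class TestLogFoldChange:
    def test_arithmetic(self):
        log2 = np.array(
            [
                [3.0, 3.0, 3.0, 1.0, 1.0, 1.0],  # means 8 vs 2 -> +2
                [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],  # equal -> 0
                [np.log2(3)] * 3 + [np.log2(12)] * 3,  # 3 vs 12 -> -2
            ]
        )
        em = expression_from_log2(log2, ["a", "b", "c"], 3, 3)
        fc = log_fold_change(em, ("gonad", "adult"))
        assert fc.to_numpy() == pytest.approx([2.0, 0.0, -2.0])
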