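import numpy as np
import pandas as pd
import pytest

from pipscan import (
    binding_expression_summary,
    bootstrap_group_p,
    overrep_fold,
    overrep_test,
    pathway_three_criteria,
    simulate_expression,
    spearman_rho,
    variance_f_test,
    welch_t,
)
from pipscan.expr_pathways import read_expression_table, read_gmt


def welch_oracle(a, b):
    """Textbook Welch formulas, written independently of the implementation."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    sa2 = np.sum((a - a.mean()) ** 2) / (len(a) - 1)
    sb2 = np.sum((b - b.mean()) ** 2) / (len(b) - 1)
    t = (a.mean() - b.mean()) / np.sqrt(sa2 / len(a) + sb2 / len(b))
    df = (sa2 / len(a) + sb2 / len(b)) ** 2 / (
        (sa2 / len(a)) ** 2 / (len(a) - 1) + (sb2 / len(b)) ** 2 / (len(b) - 1)
    )
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


class TestWelch:
    def test_identical_groups(self):
        t, _, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_gross_separation(self):
        _, _, p = welch_t([1, 2, 3], [11, 12, 13])
        assert p < 0.01

    def test_matches_formula_oracle(self):
        t, df, p = welch_t([1, 2, 3, 4], [2, 3, 4, 5])
        ot, odf, op = welch_oracle([1, 2, 3, 4], [2, 3, 4, 5])
        assert t == pytest.approx(ot, abs=1e-10)
        assert df == pytest.approx(odf, abs=1e-10)
        assert p == pytest.approx(op, abs=1e-10)

    def test_matches_oracle_on_random_fixtures(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, size=rng.integers(3, 30))
            b = rng.normal(0.5, 2, size=rng.integers(3, 30))
            got = welch_t(a, b)
            exp = welch_oracle(a, b)
            np.testing.assert_allclose(got, exp, atol=1e-10)

    def test_small_group_error(self):
        with pytest.raises(ValueError):
            welch_t([1], [1, 2])


class TestVarianceF:
    def test_identical_groups_ratio_one(self, rng):
        a = rng.normal(size=20)
        assert variance_f_test(a, a) == pytest.approx(1.0)

    def test_large_ratio_significant(self, rng):
        a = rng.normal(0, 4, size=50)
        b = rng.normal(0, 1, size=50)
        assert variance_f_test(a, b) < 0.01

    def test_null_calibration_median(self):
        ps = []
        for rep in range(200):
            local = np.random.default_rng(rep)
            ps.append(variance_f_test(local.normal(size=30), local.normal(size=30)))
        assert 0.3 < np.median(ps) < 0.7

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            variance_f_test([1.0, 1.0], [1.0, 2.0])


class TestSpearman:
    def test_monotone_limits(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]) == 1.0
        assert spearman_rho([1, 2, 3], [30, 20, 10]) == -1.0

    def test_printed_four_point_fixture(self):
        # 1 - 6*4 / (4*15) = 0.6
        assert spearman_rho([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_constant_vector_error(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])


class TestBootstrap:
    def test_identical_groups_estimate_near_half(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=200)
        p = bootstrap_group_p(a, a.copy(), trials=500, n=100, seed=1)
        assert 0.3 < p < 0.7

    def test_separated_groups_small_p(self, rng):
        a = rng.normal(0, 1, size=200)
        b = rng.normal(3, 1, size=200)
        assert bootstrap_group_p(a, b, trials=200, n=100, seed=2) < 0.01

    def test_deterministic_under_seed(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        assert bootstrap_group_p(a, b, seed=9) == bootstrap_group_p(a, b, seed=9)


class TestBindingExpressionSummary:
    def test_recovers_generator_shift(self):
        genes = [f"G{i}" for i in range(2000)]
        bound = genes[:200]
        expr = simulate_expression(genes, bound, delta=-0.5, sigma=0.3, seed=4)
        cmp_ = binding_expression_summary(expr, bound)
        assert cmp_.mean_bound > cmp_.mean_other  # -log2FC higher for bound
        assert cmp_.p < 0.05
        assert cmp_.n_bound == 200 and cmp_.n_other == 1800

    def test_null_distribution_calibrated(self):
        n_sig = 0
        genes = [f"G{i}" for i in range(500)]
        for seed in range(50):
            expr = simulate_expression(genes, genes[:50], delta=0.0, sigma=0.3,
                                       seed=seed)
            cmp_ = binding_expression_summary(expr, genes[:50])
            n_sig += cmp_.p < 0.05
        assert n_sig / 50 <= 0.05 + 2.576 * np.sqrt(0.05 * 0.95 / 50)

    def test_single_bound_gene_error(self):
        expr = pd.DataFrame({"gene": ["a", "b", "c"], "log2fc": [0, 1, 2],
                             "p": [0.5, 0.5, 0.5]})
        with pytest.raises(ValueError):
            binding_expression_summary(expr, ["a"])

    def test_missing_expression_counted(self):
        expr = pd.DataFrame({"gene": ["a", "b", "c", "d"],
                             "log2fc": [0.0, -1.0, 0.1, 0.2],
                             "p": [0.5] * 4})
        cmp_ = binding_expression_summary(expr, ["a", "b", "zzz"])
        assert cmp_.n_missing_expression == 1


class TestPathwayThreeCriteria:
    def _expression(self, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"G{i}" for i in range(400)]
        log2fc = rng.normal(0, 0.3, size=400)
        # pathway P_EFFECT = genes 0..19, bound genes 0..9 get extra knockdown
        log2fc[:10] -= 0.8
        return pd.DataFrame({"gene": genes, "log2fc": log2fc, "p": 0.5})

    def test_constructed_effect_pathway_flagged(self):
        expr = self._expression()
        pathways = {
            "P_EFFECT": {f"G{i}" for i in range(20)},
            "P_ONEBOUND": {f"G{i}" for i in range(100, 130)},
            "P_NULL": {f"G{i}" for i in range(200, 240)},
        }
        bound = {f"G{i}" for i in range(10)} | {"G100"} | {"G200", "G201"}
        results = {r.pathway: r for r in pathway_three_criteria(pathways, expr, bound)}
        assert results["P_EFFECT"].candidate
        assert results["P_ONEBOUND"].excluded
        assert results["P_ONEBOUND"].reason == "fewer than 2 bound genes"
        assert not results["P_NULL"].candidate

    def test_excluded_plus_tested_equals_total(self):
        expr = self._expression()
        pathways = {f"P{i}": {f"G{j}" for j in range(i * 10, i * 10 + 10)}
                    for i in range(30)}
        bound = {f"G{i}" for i in range(10)}
        results = pathway_three_criteria(pathways, expr, bound)
        assert len(results) == 30
        assert sum(r.excluded for r in results) + sum(
            not r.excluded for r in results
        ) == 30

    def test_null_pathways_rarely_flagged(self):
        n_flagged = n_total = 0
        for seed in range(100):
            rng = np.random.default_rng(seed + 1000)
            genes = [f"G{i}" for i in range(300)]
            expr = pd.DataFrame(
                {"gene": genes, "log2fc": rng.normal(0, 0.3, 300), "p": 0.5}
            )
            pathways = {"P": {f"G{i}" for i in range(30)}}
            bound = {f"G{i}" for i in range(0, 300, 15)}
            (r,) = pathway_three_criteria(pathways, expr, bound)
            if not r.excluded:
                n_flagged += r.candidate
                n_total += 1
        assert n_flagged / n_total < 0.05


TABLE1_ROWS = [
    (13, 3.55, 3.66),   # VEGF signaling
    (23, 7.41, 3.10),   # FGF signaling
    (17, 5.24, 3.24),   # Endothelin signaling
    (22, 7.83, 2.81),   # EGF receptor signaling
    (18, 6.81, 2.64),   # Gq/Go-mediated signaling
    (32, 10.23, 3.13),  # Cadherin signaling
    (46, 18.62, 2.47),  # Wnt signaling
    (1012, 1099.83, 0.92),  # Unclassified
]


class TestOverrepresentation:
    @pytest.mark.parametrize("found,expected,fold", TABLE1_ROWS)
    def test_fold_reproduces_printed_values(self, found, expected, fold):
        assert round(overrep_fold(found, expected), 2) == fold

    def test_found_equals_expected(self):
        assert overrep_fold(10, 10.0) == 1.00

    def test_expected_zero_error(self):
        with pytest.raises(ValueError):
            overrep_fold(5, 0.0)

    def test_binomial_tail_matches_oracle(self):
        from scipy.stats import binom

        df = overrep_test({"cat": 30}, {"cat": 2000}, list_size=100,
                          genome_size=20_000)
        expected_p = binom.sf(29, 100, 0.1)
        assert df.loc[0, "p_raw"] == pytest.approx(expected_p, rel=1e-9)
        assert df.loc[0, "p_raw"] < 1e-5

    def test_observed_equals_expected_not_significant(self):
        df = overrep_test({"cat": 10}, {"cat": 2000}, list_size=100,
                          genome_size=20_000)
        assert df.loc[0, "p_raw"] > 0.3
        assert not df.loc[0, "significant"]

    def test_single_category_bonferroni_identity(self):
        df = overrep_test({"cat": 30}, {"cat": 2000}, list_size=100,
                          genome_size=20_000)
        assert df.loc[0, "p_bonferroni"] == df.loc[0, "p_raw"]

    def test_unknown_category_skipped(self):
        df = overrep_test({"cat": 3, "ghost": 2}, {"cat": 100}, 10, 1000)
        assert df["category"].tolist() == ["cat"]


class TestTableIO:
    def test_expression_probe_collapse(self, tmp_path):
        f = tmp_path / "e.tsv"
        f.write_text("gene\tlog2fc\tp\nA\t-1.0\t0.01\nA\t0.5\t0.2\nB\t0.1\t0.9\n")
        df = read_expression_table(f)
        assert len(df) == 2
        assert df.set_index("gene").loc["A", "log2fc"] == -1.0

    def test_gmt_reader(self, tmp_path):
        f = tmp_path / "p.gmt"
        f.write_text("P1\tdesc\tA\tB\tC\nP2\tdesc\tB\n")
        assert read_gmt(f) == {"P1": {"A", "B", "C"}, "P2": {"B"}}
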