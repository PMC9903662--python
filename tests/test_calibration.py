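"""Phenotype simulation, score tests, lambda GC, filters, thresholds, pruning."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import statsmodels.api as sm
from hypothesis import given, strategies as st
from scipy import stats

from svcrkit.calibration import (
    PhenotypeMatrix,
    ScoreTester,
    burden_score,
    burden_test,
    empirical_thresholds,
    expected_ac_filter,
    expected_allele_count,
    gene_synonymous_lambda_table,
    lambda_gc,
    phenotype_lambda_table,
    prune_correlated_phenotypes,
    qc_gate,
    simulate_random_phenotypes,
    single_variant_score_test,
)
from svcrkit.synthetic import Grm


def identity_grm(n):
    return Grm([f"s{i}" for i in range(n)], sp.identity(n, format="csr"))


def trio_grm():
    block = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, 0.5], [0.5, 0.5, 1.0]])
    full = np.block(
        [[block, np.zeros((3, 3))], [np.zeros((3, 3)), block]]
    )
    return Grm([f"s{i}" for i in range(6)], sp.csr_matrix(full))


class TestSimulatePhenotypes:
    def test_identity_grm_full_heritability_is_iid_standard_normal(self):
        pm = simulate_random_phenotypes(identity_grm(4000), 1, [1.0], seed=3)
        y = pm.values.iloc[:, 0].to_numpy()
        assert abs(y.mean()) < 4 / np.sqrt(len(y))
        assert abs(y.std() - 1) < 0.05
        assert stats.kstest(y, "norm").pvalue > 0.01

    def test_binary_prevalence_exact_case_count(self):
        pm = simulate_random_phenotypes(identity_grm(2000), 0, [], [0.1], seed=5)
        col = pm.values.iloc[:, 0]
        assert col.sum() == 200  # floor(0.1 * 2000), exact by construction
        assert pm.meta.iloc[0]["n_cases"] == 200

    def test_covariance_recovery_under_family_grm(self):
        """Empirical covariance of replicated draws matches h2*GRM + (1-h2)*I."""
        grm = trio_grm()
        h2 = 0.6
        pm = simulate_random_phenotypes(grm, 2000, [h2], seed=7)
        y = pm.values.to_numpy()  # samples x replicates
        emp = np.cov(y)
        expected = h2 * grm.to_dense() + (1 - h2) * np.eye(6)
        se = 1.5 / np.sqrt(2000)  # loose Monte-Carlo scale for covariance entries
        assert np.max(np.abs(emp - expected)) < 4 * se

    def test_zero_heritability_ignores_grm(self):
        grm = trio_grm()
        pm = simulate_random_phenotypes(grm, 1500, [0.0], seed=9)
        y = pm.values.to_numpy()
        related = np.corrcoef(y[0], y[2])[0, 1]  # parent-offspring pair
        assert abs(related) < 3 / np.sqrt(1500)

    def test_invalid_heritability_rejected(self):
        with pytest.raises(ValueError, match="heritability"):
            simulate_random_phenotypes(identity_grm(5), 1, [1.5], seed=0)

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValueError, match="prevalence"):
            simulate_random_phenotypes(identity_grm(5), 0, [], [0.7], seed=0)


class TestScoreTest:
    def _null_data(self, n=600, seed=0):
        rng = np.random.default_rng(seed)
        g = rng.binomial(2, 0.3, size=n).astype(float)
        y = rng.standard_normal(n)
        cov = np.column_stack([rng.normal(55, 8, n), rng.integers(0, 2, n)])
        return g, y, cov

    def test_permutation_of_sample_order_preserves_p(self):
        g, y, cov = self._null_data()
        p1, *_ = single_variant_score_test(g, y, cov)
        perm = np.random.default_rng(1).permutation(len(g))
        p2, *_ = single_variant_score_test(g[perm], y[perm], cov[perm])
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_strong_effect_matches_full_regression_fit(self):
        rng = np.random.default_rng(2)
        n = 2000
        g = rng.binomial(2, 0.2, size=n).astype(float)
        cov = rng.standard_normal((n, 2))
        y = 1.0 * g + cov @ [0.3, -0.2] + rng.standard_normal(n)
        p, beta, se = single_variant_score_test(g, y, cov)
        assert p < 1e-10 and beta > 0
        x = sm.add_constant(np.column_stack([cov, g]))
        fit = sm.OLS(y, x).fit()
        assert beta == pytest.approx(fit.params[-1], rel=1e-3)

    def test_binary_trait_matches_logistic_fit(self):
        rng = np.random.default_rng(3)
        n = 3000
        g = rng.binomial(2, 0.3, size=n).astype(float)
        logit = -1.0 + 0.8 * g
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        p, beta, se = single_variant_score_test(g, y, trait_type="binary")
        fit = sm.Logit(y, sm.add_constant(g)).fit(disp=0)
        assert p < 1e-10
        assert beta == pytest.approx(fit.params[1], rel=0.15)  # score-test approx

    def test_zero_variance_variant_flagged(self):
        _, y, cov = self._null_data()
        with pytest.raises(ValueError, match="zero genotype variance"):
            single_variant_score_test(np.ones_like(y), y, cov)

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(4)
        n, m = 800, 1200
        g = rng.binomial(2, rng.uniform(0.05, 0.5, size=m), size=(n, m)).astype(float)
        y = rng.standard_normal(n)
        res = ScoreTester(y).test_many(g)
        for alpha in (0.05, 0.01):
            rate = (res["p"] < alpha).mean()
            se = np.sqrt(alpha * (1 - alpha) / m)
            assert abs(rate - alpha) < 3 * se


class TestBurden:
    def test_single_qualifying_variant_excluded(self):
        g = np.array([[1.0, 0, 0, 0], [0, 0, 1.0, 0]])
        afs = np.array([0.005, 0.2])  # only the first is rare enough
        y = np.array([0.1, -0.2, 0.3, 0.0])
        with pytest.raises(ValueError, match="group excluded"):
            burden_test(g, afs, y)

    def test_common_variant_excluded_from_score(self):
        g = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0], [2.0, 2, 2, 2]])
        afs = np.array([0.005, 0.008, 0.05])
        score, keep = burden_score(g, afs)
        assert list(keep) == [True, True, False]
        assert list(score) == [1.0, 1.0, 0.0, 0.0]

    def test_disjoint_carriers_equal_summed_dosage_test(self):
        rng = np.random.default_rng(5)
        n = 400
        g1 = np.zeros(n)
        g2 = np.zeros(n)
        g1[:12] = 1.0
        g2[20:30] = 1.0
        y = rng.standard_normal(n)
        p_group, *_ = burden_test(
            np.vstack([g1, g2]), np.array([0.008, 0.008]), y
        )
        p_single, *_ = single_variant_score_test(g1 + g2, y)
        assert p_group == pytest.approx(p_single, rel=1e-9)

    def test_major_allele_flip_counts_minor_copies(self):
        g = np.array([[2.0, 2, 2, 1]])
        afs = np.array([0.996])
        score, keep = burden_score(g, afs)
        assert keep[0]
        assert list(score) == [0.0, 0, 0, 1.0]


class TestLambdaGc:
    def test_all_half_is_exactly_one(self):
        assert lambda_gc([0.5] * 10) == pytest.approx(1.0)

    def test_uniform_grid_is_one(self):
        grid = np.linspace(1e-4, 1 - 1e-4, 10_001)
        assert lambda_gc(grid) == pytest.approx(1.0, abs=1e-3)

    def test_all_ones_is_zero(self):
        assert lambda_gc([1.0, 1.0]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            lambda_gc([])


class TestExpectedAc:
    def test_biobank_scale_arithmetic(self):
        # median rare-LoF-class CAF at biobank scale clears the cutoff
        assert expected_allele_count(1.5e-4, 394_841) == pytest.approx(59.2, abs=0.05)

    def test_filtering_rules(self):
        rec = pd.DataFrame(
            {
                "freq": [1.5e-4, 1e-4, 0.0, np.nan],
                "n_eff": [394_841, 400_000, 1000, 1000],
            }
        )
        kept, removed = expected_ac_filter(rec)
        assert list(kept.index) == [0]
        assert kept["expected_ac"].iloc[0] == pytest.approx(59.22615)
        reasons = removed.set_index(removed.index)["removed_reason"]
        assert reasons.loc[3] == "missing_freq"
        assert reasons.loc[1] == "low_expected_ac"  # 40 < 50
        assert reasons.loc[2] == "low_expected_ac"  # CAF 0


class TestEmpiricalThresholds:
    @pytest.mark.parametrize(
        "p_tilde,threshold",
        [(5e-6, 2.5e-7), (1.6e-7, 8e-9), (1.3e-5, 6.5e-7), (1.0, 0.05)],
    )
    def test_threshold_is_five_percent_of_median_min_p(self, p_tilde, threshold):
        eff, thr = empirical_thresholds([p_tilde])
        assert thr == pytest.approx(threshold)
        assert eff == pytest.approx(1.0 / p_tilde)

    def test_median_across_phenotypes(self):
        eff, thr = empirical_thresholds([1e-6, 5e-6, 9e-6])
        assert thr == pytest.approx(0.05 * 5e-6)

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=20))
    def test_monotone_in_median(self, ps):
        eff, thr = empirical_thresholds(ps)
        eff2, thr2 = empirical_thresholds([p / 2 for p in ps])
        assert thr2 <= thr and eff2 >= eff


def _records():
    rng = np.random.default_rng(6)
    rows = []
    for pheno in ("ph_good", "ph_bad"):
        for gene in ("G1", "G2", "G3"):
            for fclass in ("pLoF", "synonymous"):
                for k in range(30):
                    p = rng.random() if pheno == "ph_good" else rng.uniform(0.8, 1.0)
                    rows.append(
                        {
                            "phenotype": pheno,
                            "unit": f"{gene}|{fclass}",
                            "gene": gene,
                            "functional_class": fclass,
                            "test": "burden",
                            "p": p if gene != "G2" else min(1.0, p + 0.7),
                            "beta": 0.0,
                            "se": 1.0,
                            "freq": 0.3,
                            "n_eff": 1000,
                        }
                    )
    return pd.DataFrame(rows)


class TestQcGate:
    def _inputs(self):
        rec = _records()
        gene_lam = gene_synonymous_lambda_table(rec)
        gene_table = pd.DataFrame(
            {
                "gene": ["G1", "G2", "G3"],
                "mean_coverage": [30.0, 30.0, 10.0],
                "synonymous_lambda": [gene_lam["G1"], 0.6, gene_lam["G3"]],
            }
        )
        return rec, gene_table

    def test_low_synonymous_lambda_gene_removed(self):
        rec, gene_table = self._inputs()
        lambdas = {"ph_good": 1.0, "ph_bad": 1.0}
        kept, audit = qc_gate(rec, gene_table, lambdas)
        assert "G2" not in set(kept["gene"])
        assert audit["gene_synonymous_lambda"] > 0

    def test_low_coverage_gene_removed(self):
        rec, gene_table = self._inputs()
        kept, _ = qc_gate(rec, gene_table, {"ph_good": 1.0, "ph_bad": 1.0})
        assert "G3" not in set(kept["gene"])

    def test_zero_se_records_removed(self):
        rec, gene_table = self._inputs()
        rec.loc[rec.index[:5], "se"] = 0.0
        kept, audit = qc_gate(rec, gene_table, {"ph_good": 1.0, "ph_bad": 1.0})
        assert audit["se_zero"] == 5

    def test_deflated_phenotype_removed(self):
        rec, gene_table = self._inputs()
        lambdas = phenotype_lambda_table(rec).to_dict()
        assert lambdas["ph_bad"] < 0.75  # p-values piled near 1 deflate lambda
        kept, _ = qc_gate(rec, gene_table, lambdas)
        assert "ph_bad" not in set(kept["phenotype"])

    def test_vacuous_filters_identity_and_idempotent(self):
        rec, gene_table = self._inputs()
        gene_table["mean_coverage"] = 30.0
        gene_table["synonymous_lambda"] = 1.0
        lambdas = {"ph_good": 1.0, "ph_bad": 1.0}
        once, _ = qc_gate(rec, gene_table, lambdas, ac_threshold=0.0)
        pd.testing.assert_frame_equal(
            once.drop(columns="expected_ac"), rec.reset_index(drop=True)
        )
        twice, _ = qc_gate(once, gene_table, lambdas, ac_threshold=0.0)
        pd.testing.assert_frame_equal(once, twice)

    def test_idempotent_with_active_filters(self):
        rec, gene_table = self._inputs()
        lambdas = phenotype_lambda_table(rec).to_dict()
        once, _ = qc_gate(rec, gene_table, lambdas)
        twice, _ = qc_gate(once, gene_table, lambdas)
        pd.testing.assert_frame_equal(once, twice)


class TestPrunePhenotypes:
    def _pm(self, cols: dict, meta_rows: list[dict]) -> PhenotypeMatrix:
        values = pd.DataFrame(cols)
        meta = pd.DataFrame(meta_rows).set_index("phenotype")
        return PhenotypeMatrix(values, meta)

    def test_identical_binaries_keep_more_cases(self):
        rng = np.random.default_rng(7)
        base = (rng.random(400) < 0.5).astype(float)
        pm = self._pm(
            {"few": base, "many": base},
            [
                {"phenotype": "few", "trait_type": "binary", "h2": 1.0,
                 "prevalence": 0.5, "n_cases": 100, "n_defined": 400},
                {"phenotype": "many", "trait_type": "binary", "h2": 1.0,
                 "prevalence": 0.5, "n_cases": 200, "n_defined": 400},
            ],
        )
        kept, edges = prune_correlated_phenotypes(pm)
        assert kept == {"many"}
        assert len(edges) == 1

    def test_orthogonal_columns_all_kept(self):
        rng = np.random.default_rng(8)
        cols = {f"p{i}": rng.standard_normal(500) for i in range(4)}
        meta = [
            {"phenotype": f"p{i}", "trait_type": "continuous", "h2": 1.0,
             "prevalence": np.nan, "n_cases": np.nan, "n_defined": 500}
            for i in range(4)
        ]
        kept, edges = prune_correlated_phenotypes(self._pm(cols, meta))
        assert kept == set(cols)
        assert edges.empty

    def test_kept_set_has_pairwise_r2_below_cutoff(self):
        rng = np.random.default_rng(9)
        base = rng.standard_normal(300)
        cols = {
            "a": base,
            "b": base + 0.1 * rng.standard_normal(300),
            "c": rng.standard_normal(300),
            "d": -base + 0.1 * rng.standard_normal(300),
        }
        meta = [
            {"phenotype": k, "trait_type": "continuous", "h2": 1.0,
             "prevalence": np.nan, "n_cases": np.nan, "n_defined": 300}
            for k in cols
        ]
        pm = self._pm(cols, meta)
        kept, _ = prune_correlated_phenotypes(pm)
        z = (pm.values - pm.values.mean()) / pm.values.std(ddof=0)
        for a in kept:
            for b in kept:
                if a < b:
                    r2 = (z[a] @ z[b] / len(z)) ** 2
                    assert r2 <= 0.5
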