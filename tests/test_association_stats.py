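import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alcprs import reference
from alcprs.association_stats import (
    allele_frequencies,
    bh_fdr,
    contingency_test,
    crude_odds_ratio,
    encode_genetic_model,
    firth_fit,
    genotype_association,
    hwe_chi_square,
    logistic_ml_fit,
)

cell_counts = st.integers(min_value=0, max_value=60)


def expand_2x2(a, b, c, d):
    """Per-observation design/outcome for the 2x2 table [[a,b],[c,d]]."""
    X = np.array([[1.0, 1.0], [1.0, 0.0], [1.0, 1.0], [1.0, 0.0]])
    y = np.array([1.0, 1.0, 0.0, 0.0])
    w = np.array([a, b, c, d], dtype=float)
    return X, y, w


class TestFrequencies:
    @pytest.mark.parametrize(
        "counts, exp_count, exp_freq",
        [
            ((40, 49, 29), 107, 0.4534),   # PNPLA3 G in cases
            ((111, 18, 2), 22, 0.0840),    # TM6SF2 T in controls
            ((10, 0, 0), 0, 0.0),          # monomorphic
        ],
    )
    def test_direct_counting(self, counts, exp_count, exp_freq):
        count, freq = allele_frequencies(counts)
        assert count == exp_count
        assert freq == pytest.approx(exp_freq, abs=5e-5)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            allele_frequencies((0, 0, 0))


class TestHWE:
    @pytest.mark.parametrize(
        "counts, expected_p",
        [
            ((40, 49, 29), 0.078),   # cases, PNPLA3
            ((74, 50, 7), 0.699),    # controls, PNPLA3
            ((81, 32, 5), 0.427),    # cases, TM6SF2
            ((111, 18, 2), 0.221),   # controls, TM6SF2
        ],
    )
    def test_published_cohorts_to_three_decimals(self, counts, expected_p):
        assert hwe_chi_square(counts).p_value == pytest.approx(expected_p, abs=5e-4)

    def test_exact_hwe_proportions_give_zero_statistic(self):
        res = hwe_chi_square((25, 50, 25))
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_monomorphic_flagged_untestable(self):
        res = hwe_chi_square((30, 0, 0))
        assert not res.testable and res.chi_square == 0.0 and res.p_value == 1.0


class TestContingency:
    def test_allele_table_chi_square(self):
        # TM6SF2 T-allele counts, cases vs controls
        res = contingency_test([[42, 194], [22, 240]], method="chi2")
        assert res.statistic == pytest.approx(9.79, abs=0.01)
        assert res.p_value == pytest.approx(0.0018, abs=2e-4)

    def test_sparse_2x2_routes_to_fisher(self):
        res = contingency_test([[5, 113], [2, 129]], method="auto")
        assert res.method == "fisher"
        assert res.p_value > 0.05

    def test_independence_gives_unit_p(self):
        res = contingency_test([[10, 10], [10, 10]], method="chi2")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_fisher_on_2x3_unsupported(self):
        with pytest.raises(ValueError, match="2x2"):
            contingency_test([[1, 2, 3], [4, 5, 6]], method="fisher")

    @given(
        st.lists(st.lists(cell_counts, min_size=2, max_size=2), min_size=2, max_size=2)
    )
    @settings(max_examples=50, deadline=None)
    def test_chi2_invariant_to_permutation(self, table):
        t = np.array(table)
        if t.sum() == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            return
        base = contingency_test(t, method="chi2").statistic
        assert contingency_test(t[::-1], method="chi2").statistic == pytest.approx(base)
        assert contingency_test(t[:, ::-1], method="chi2").statistic == pytest.approx(base)


class TestCrudeOddsRatio:
    def test_dominant_pnpla3_cross_product(self):
        res = crude_odds_ratio([[78, 40], [57, 74]])
        assert res.estimate == pytest.approx(5772 / 2280, rel=1e-12)
        lo, hi = res.ci95
        assert lo < res.estimate < hi

    def test_symmetric_table_is_null(self):
        assert crude_odds_ratio([[1, 1], [1, 1]]).estimate == pytest.approx(1.0)

    def test_haldane_correction_with_zero_cell(self):
        res = crude_odds_ratio([[0, 10], [5, 10]], haldane=True)
        assert res.estimate == pytest.approx((0.5 * 10.5) / (10.5 * 5.5), rel=1e-12)

    def test_zero_cell_without_correction_flagged(self):
        res = crude_odds_ratio([[0, 10], [5, 10]], haldane=False)
        assert res.estimate == 0.0 and res.ci95 is None


class TestGeneticModelCoding:
    @pytest.mark.parametrize(
        "g, model, expected",
        [
            (0, "additive", 0), (1, "additive", 1), (2, "additive", 2),
            (1, "dominant", 1), (0, "dominant", 0),
            (1, "recessive", 0), (2, "recessive", 1),
            (1, "genotypic", (1, 0)), (2, "genotypic", (0, 1)),
        ],
    )
    def test_codings(self, g, model, expected):
        assert encode_genetic_model(g, model) == expected

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            encode_genetic_model(3, "additive")


class TestLogisticML:
    def test_saturated_model_matches_crude_or(self):
        X, y, w = expand_2x2(78, 40, 57, 74)
        fit = logistic_ml_fit(X, y, weights=w)
        assert np.exp(fit.params[1]) == pytest.approx(5772 / 2280, abs=1e-6)
        assert fit.converged and not fit.separation

    @given(st.tuples(*[st.integers(1, 60)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_saturated_equivalence_on_random_positive_tables(self, cells):
        a, b, c, d = cells
        fit = logistic_ml_fit(*expand_2x2(a, b, c, d)[:2],
                              weights=np.array([a, b, c, d], float))
        assert np.exp(fit.params[1]) == pytest.approx(a * d / (b * c), abs=1e-6)

    def test_perfect_separation_flagged(self):
        X = np.array([[1, 0], [1, 0], [1, 1], [1, 1]], dtype=float)
        y = np.array([0.0, 0.0, 1.0, 1.0])
        fit = logistic_ml_fit(X, y)
        assert fit.separation

    def test_rank_deficiency_rejected(self):
        X = np.array([[1, 1, 0], [1, 1, 0], [1, 1, 0], [1, 1, 0]], dtype=float)
        y = np.array([0.0, 1.0, 0.0, 1.0])
        with pytest.raises(np.linalg.LinAlgError):
            logistic_ml_fit(X, y)

    def test_matches_statsmodels_on_multivariate_fit(self, rng):
        import statsmodels.api as sm

        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.integers(0, 2, n)])
        eta = 0.3 + 0.8 * X[:, 1] - 0.5 * X[:, 2]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        ours = logistic_ml_fit(X, y)
        theirs = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(ours.params, theirs.params, atol=1e-6)
        np.testing.assert_allclose(ours.se, theirs.bse, atol=1e-6)


class TestFirth:
    def test_sparse_2x2_matches_haldane_oracle(self):
        X, y, w = expand_2x2(5, 81, 2, 111)
        fit = firth_fit(X, y, weights=w)
        assert np.exp(fit.params[1]) == pytest.approx(
            (5.5 * 111.5) / (81.5 * 2.5), abs=1e-6
        )

    def test_separated_data_stays_finite(self):
        X = np.array([[1, 0], [1, 0], [1, 1], [1, 1]], dtype=float)
        y = np.array([0.0, 0.0, 1.0, 1.0])
        fit = firth_fit(X, y)
        assert fit.params[1] == pytest.approx(np.log(25), abs=1e-6)

    def test_balanced_null_table_has_zero_slope(self):
        X, y, w = expand_2x2(10, 10, 10, 10)
        fit = firth_fit(X, y, weights=w)
        assert fit.params[1] == pytest.approx(0.0, abs=1e-8)

    @given(st.tuples(*[st.integers(0, 40)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_haldane_equivalence_on_random_tables(self, cells):
        a, b, c, d = cells
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        X, y, w = expand_2x2(a, b, c, d)
        keep = w > 0
        fit = firth_fit(X[keep], y[keep], weights=w[keep])
        oracle = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        assert np.exp(fit.params[1]) == pytest.approx(oracle, abs=1e-6, rel=1e-6)


class TestGenotypeAssociation:
    def test_allelic_or_from_study_reconstruction(self, study_table):
        res, = genotype_association(study_table, "rs738409", "allelic")
        # cross-product of the per-allele counts 107/129 vs 64/198
        assert res.estimate == pytest.approx((107 * 198) / (129 * 64), rel=1e-9)

    def test_dominant_crude_fit_matches_table_or(self, study_table):
        res, = genotype_association(
            study_table, "rs738409", "dominant", method="ml", adjust=()
        )
        assert res.estimate == pytest.approx(5772 / 2280, abs=1e-5)
        assert res.method == "ml"

    def test_sparse_recessive_auto_falls_back_to_firth(self, genotype_tsv, variants):
        # every TT homozygote is a case: the recessive indicator separates
        rows = [(f"s{i}", 60, "male", "case", "C/C", "T/T") for i in range(3)]
        rows += [(f"t{i}", 60, "male", "case", "C/C", "C/T") for i in range(10)]
        rows += [(f"u{i}", 60, "male", "control", "C/C", "C/C") for i in range(13)]
        table_path = genotype_tsv(rows)
        from alcprs.genotype_io import read_genotype_table

        table = read_genotype_table(table_path, variants)
        res, = genotype_association(
            table, "rs58542926", "recessive", method="auto", adjust=()
        )
        assert res.method == "firth"
        assert np.isfinite(res.estimate)

    def test_genotypic_model_yields_two_contrasts(self, study_table):
        results = genotype_association(study_table, "rs738409", "genotypic",
                                       method="ml", adjust=("age", "sex"))
        assert [r.term for r in results] == ["rs738409 het", "rs738409 homalt"]
        assert all(r.covariates == ("age", "sex") for r in results)
        # homozygous risk carriers at much higher odds than heterozygotes
        assert results[1].estimate > results[0].estimate > 1


class TestBhFdr:
    def test_step_up_example(self):
        d = bh_fdr([0.001, 0.01, 0.03, 0.2], q=0.05)
        assert sum(d.rejected) == 3
        assert d.threshold == pytest.approx(3 / 4 * 0.05)
        assert d.largest_rejected_p == pytest.approx(0.03)

    def test_no_rejections(self):
        d = bh_fdr([0.9, 0.8], q=0.05)
        assert not any(d.rejected) and d.threshold == 0.0

    def test_single_test_reduces_to_level(self):
        assert sum(bh_fdr([0.001], q=0.05).rejected) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([], q=0.05)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_step_up(self, ps):
        d = bh_fdr(ps, q=0.05)
        m = len(ps)
        sorted_p = sorted(ps)
        k_best = 0
        for k in range(1, m + 1):
            if sorted_p[k - 1] <= k / m * 0.05:
                k_best = k
        expected = (
            [p <= sorted_p[k_best - 1] for p in ps] if k_best else [False] * m
        )
        assert d.rejected == expected

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        ps = rng.random(40)
        d = bh_fdr(ps, q=0.05)
        reject, *_ = multipletests(ps, alpha=0.05, method="fdr_bh")
        assert d.rejected == reject.tolist()
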