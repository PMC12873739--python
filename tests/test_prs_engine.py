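import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alcprs.genotype_io import VariantDef
from alcprs.prs_engine import (
    PRSModel,
    cohort_prs_summary,
    compute_prs,
    enumerate_score_levels,
    genotype_points,
    score_table,
    strata_association,
    stratify_prs,
)
from alcprs.synthetic_data import reconstruct_from_counts
from tests.conftest import make_marginals

W1, W2 = 0.19895, 0.186567  # PGS000704 effect weights
WSUM = W1 + W2


class TestGenotypePoints:
    @pytest.mark.parametrize("g, pts", [(0, 0.0), (1, 0.5), (2, 1.0)])
    def test_point_assignment(self, g, pts):
        assert genotype_points(g) == pts

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            genotype_points(3)


class TestComputePrs:
    def test_all_wild_type_scores_zero(self, prs_model):
        assert compute_prs([0, 0], prs_model) == 0.0

    def test_double_homozygote_scores_one(self, prs_model):
        assert compute_prs([1, 1], prs_model) == pytest.approx(1.0)

    def test_single_homozygote_weight_share(self, prs_model):
        assert compute_prs([1, 0], prs_model) == pytest.approx(W1 / WSUM, abs=1e-6)

    def test_length_mismatch_rejected(self, prs_model):
        with pytest.raises(ValueError):
            compute_prs([1], prs_model)

    def test_permutation_invariance(self, prs_model):
        flipped = PRSModel(list(reversed(prs_model.variants)))
        for p1, p2 in itertools.product([0, 0.5, 1], repeat=2):
            assert compute_prs([p1, p2], prs_model) == pytest.approx(
                compute_prs([p2, p1], flipped)
            )

    def test_exactly_nine_score_levels(self, prs_model):
        levels = enumerate_score_levels(prs_model)
        brute = sorted(
            {
                (W1 * p1 + W2 * p2) / WSUM
                for p1 in (0, 0.5, 1)
                for p2 in (0, 0.5, 1)
            }
        )
        assert len(levels) == 9
        np.testing.assert_allclose(levels, brute, atol=1e-12)

    def test_adding_a_risk_allele_never_decreases_the_score(self, prs_model):
        for g1, g2 in itertools.product(range(3), repeat=2):
            base = compute_prs([g1 / 2, g2 / 2], prs_model)
            if g1 < 2:
                assert compute_prs([(g1 + 1) / 2, g2 / 2], prs_model) >= base
            if g2 < 2:
                assert compute_prs([g1 / 2, (g2 + 1) / 2], prs_model) >= base


class TestCohortSummary:
    def test_study_reconstruction_means(self, study_table, prs_model):
        scores = score_table(study_table, prs_model)
        ph = study_table.data["phenotype"]
        summary = cohort_prs_summary(scores[ph == "case"], scores[ph == "control"])
        assert summary.case_mean == pytest.approx(0.320, abs=5e-4)
        assert summary.control_mean == pytest.approx(0.167, abs=5e-4)
        assert summary.p_value < 1e-5

    def test_mean_invariant_across_couplings(self, study_marginals, prs_model):
        means = []
        for coupling in (1.0, 100.0, 0.01):
            t = reconstruct_from_counts(study_marginals, coupling_or=coupling, seed=5)
            s = score_table(t, prs_model)
            ph = t.data["phenotype"]
            means.append((s[ph == "case"].mean(), s[ph == "control"].mean()))
        for m in means[1:]:
            assert m == pytest.approx(means[0], abs=1e-12)

    def test_mean_equals_weighted_marginal_means(self, study_marginals, prs_model):
        # the cohort mean needs only the per-locus marginals:
        # mean = sum_i w_i * mean(points_i), w_i = beta_i / sum(beta)
        t = reconstruct_from_counts(study_marginals, coupling_or=7.5, seed=1)
        case = t.subset("case")
        s = score_table(case, prs_model)
        expected = sum(
            v.effect_weight
            / prs_model.normalizer
            * np.mean([g / 2 for g in case.data[v.rsid].astype(float)])
            for v in prs_model.variants
        )
        assert s.mean() == pytest.approx(expected, abs=1e-12)

    def test_exact_rank_sum_enumeration(self):
        summary = cohort_prs_summary([1.0, 2.0], [3.0, 4.0])
        assert summary.method == "exact"
        assert summary.p_value == pytest.approx(1 / 3)

    def test_identical_groups_not_significant(self):
        scores = [0.1, 0.2, 0.3, 0.4]
        summary = cohort_prs_summary(scores, scores)
        assert summary.p_value == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cohort_prs_summary([], [0.1])

    @given(
        st.lists(st.integers(0, 8), min_size=2, max_size=7),
        st.lists(st.integers(0, 8), min_size=2, max_size=7),
    )
    @settings(max_examples=60, deadline=None)
    def test_exact_path_matches_permutation_oracle(self, xs, ys):
        from itertools import combinations
        from math import comb

        from scipy.stats import rankdata

        summary = cohort_prs_summary(xs, ys)
        pooled = np.array(xs + ys, dtype=float)
        ranks = rankdata(pooled)
        n1, n = len(xs), len(pooled)
        mu = n1 * (n - n1) / 2
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        hits = sum(
            1
            for idx in combinations(range(n), n1)
            if abs(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2 - mu)
            >= abs(u_obs - mu) - 1e-12
        )
        assert summary.p_value == pytest.approx(hits / comb(n, n1))


class TestStratification:
    @pytest.mark.parametrize(
        "score, stratum",
        [
            (0.0, "low"),                       # double wild type
            (0.5 * W1 / WSUM, "moderate"),      # PNPLA3 het only: 0.2580
            (0.5 * W2 / WSUM, "moderate"),      # TM6SF2 het only: 0.2420
            (W1 / WSUM, "high"),                # PNPLA3 homozygote: 0.5161
            (1.0, "high"),
        ],
    )
    def test_published_cutpoint_assignment(self, score, stratum):
        s = pd.Series([score])
        assert stratify_prs(s, 0.26).labels.iloc[0] == stratum

    def test_strata_partition_all_subjects(self, study_table, prs_model):
        scores = score_table(study_table, prs_model)
        strata = stratify_prs(scores, 0.26)
        assert sum(strata.sizes.values()) == len(scores)
        low_ids = strata.labels[strata.labels == "low"].index
        assert (scores[low_ids] == 0).all()

    def test_bad_cutpoint_rejected(self):
        with pytest.raises(ValueError):
            stratify_prs(pd.Series([0.1]), 0.0)


class TestStrataAssociation:
    def test_low_stratum_is_fixed_reference(self, study_table, prs_model):
        scores = score_table(study_table, prs_model)
        strata = stratify_prs(scores, 0.26)
        results = strata_association(strata, study_table)
        assert results[0].term == "low" and results[0].estimate == 1.0
        terms = {r.term for r in results}
        assert {"moderate", "high"} <= terms
        high = next(r for r in results if r.term == "high")
        assert high.estimate > 1 and high.ci95[0] > 1  # clear risk gradient

    def test_null_cohort_strata_ors_near_one(self, prs_model):
        # same marginals in both cohorts: no genotype-outcome dependence
        marginals = make_marginals([60, 40, 20], [60, 40, 20])
        t = reconstruct_from_counts(marginals, seed=2)
        scores = score_table(t, prs_model)
        strata = stratify_prs(scores, 0.26)
        for res in strata_association(strata, t)[1:]:
            lo, hi = res.ci95
            assert lo < 1 < hi

    def test_empty_low_stratum_rejected(self, prs_model):
        marginals = make_marginals([0, 60, 60], [0, 60, 60])
        t = reconstruct_from_counts(marginals, seed=2)
        scores = score_table(t, prs_model)
        strata = stratify_prs(scores, 0.26)
        with pytest.raises(ValueError, match="reference"):
            strata_association(strata, t)
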