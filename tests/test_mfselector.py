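"""The DE_total statistic, permutation inference and BH correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from megselect import (
    ExpressionMatrix,
    bh_qvalues,
    de_total,
    discriminating_error,
    permutation_pvalues,
    select_megs,
)
from megselect.exceptions import DomainError
from megselect.mfselector import _PresortedMatrix

from conftest import brute_force_de_total, make_labeling, random_instance


class TestDiscriminatingError:
    @pytest.mark.parametrize(
        "lower, upper, expect_e, expect_t",
        [
            ((1, 2), (10, 11), 0, 2),  # perfectly separated
            ((1, 10), (2, 3), 1, 1),  # enumeration: t=1 -> 1 error, t=10 -> 2
            ((5, 5), (5, 5), 2, 5),  # single candidate; tied upper counts as errors
        ],
    )
    def test_ascending_examples(self, lower, upper, expect_e, expect_t):
        res = discriminating_error(np.array(lower, float), np.array(upper, float))
        assert res.e_k == expect_e
        assert res.threshold == expect_t

    def test_descending_is_ascending_on_negated_values(self):
        lower = np.array([10.0, 9.0])
        upper = np.array([1.0, 2.0])
        res = discriminating_error(lower, upper, "descending")
        assert res.e_k == 0
        assert res.threshold == 9.0  # smallest negated candidate maps back to 9

    def test_threshold_is_a_lower_group_value(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            lower = rng.normal(size=rng.integers(1, 8))
            upper = rng.normal(size=rng.integers(1, 8))
            res = discriminating_error(lower, upper)
            assert res.threshold in lower

    def test_empty_group_is_an_error(self):
        with pytest.raises(DomainError):
            discriminating_error(np.array([]), np.array([1.0]))


class TestDETotal:
    def test_perfect_ascending_scores_zero(self):
        lab = make_labeling([1, 2, 3, 4])
        score = de_total(np.array([1.0, 2.0, 3.0, 4.0]), lab)
        assert score.de_total == 0
        assert len(score.splits) == 3

    def test_reversed_values_score_maximal(self):
        lab = make_labeling([1, 2, 3, 4])
        score = de_total(np.array([4.0, 3.0, 2.0, 1.0]), lab)
        assert [s.e_k for s in score.splits] == [3, 2, 1]
        assert score.de_total == 6

    def test_constant_gene_is_not_monotone(self):
        lab = make_labeling([1, 2, 3, 4])
        score = de_total(np.array([5.0, 5.0, 5.0, 5.0]), lab)
        assert score.de_total == 6

    def test_series_input_requires_every_labeled_sample(self):
        lab = make_labeling([1, 1, 2, 2])
        values = pd.Series([1.0, 2.0, 3.0], index=["s1", "s2", "s3"])
        with pytest.raises(DomainError):
            de_total(values, lab)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            values, levels = random_instance(rng)
            lab = make_labeling(levels)
            fast = _PresortedMatrix(values[None, :]).de_totals(levels)[0]
            slow = de_total(values, lab).de_total
            ref = brute_force_de_total(values, levels)
            assert fast == ref
            assert slow == ref

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_rank_invariance(self, seed):
        rng = np.random.default_rng(seed)
        values, levels = random_instance(rng)
        lab = make_labeling(levels)
        base = de_total(values, lab).de_total
        for transform in (np.exp, lambda v: 0.1 * v - 3, np.cbrt):
            assert de_total(transform(values), lab).de_total == base

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_direction_duality_on_tie_free_values(self, seed):
        rng = np.random.default_rng(seed)
        values, levels = random_instance(rng, with_ties=False)
        lab = make_labeling(levels)
        desc = de_total(values, lab, "descending").de_total
        asc_neg = de_total(-values, lab, "ascending").de_total
        assert desc == asc_neg


def _expr_matrix(values, sample_ids=None):
    values = np.asarray(values, dtype=float)
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(values.shape[1])]
    genes = [f"g{i + 1}" for i in range(values.shape[0])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sample_ids))


class TestPermutationPvalues:
    def test_pvalues_live_on_the_add_one_grid(self):
        rng = np.random.default_rng(1)
        expr = _expr_matrix(rng.normal(size=(30, 16)))
        lab = make_labeling(np.repeat([1, 2, 3, 4], 4))
        B = 100
        p = permutation_pvalues(expr, lab, B=B, seed=9)
        grid = np.arange(1, B + 2) / (B + 1)
        assert np.isin(p.to_numpy(), grid).all()
        assert (p > 0).all() and (p <= 1).all()

    def test_maximal_score_gets_p_one(self):
        # observed DE_total is the worst achievable, so every permutation ties
        # or beats it
        expr = _expr_matrix([[1.0, 0.0]])
        lab = make_labeling([1, 2])
        p = permutation_pvalues(expr, lab, B=50, seed=2)
        assert p.iloc[0] == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        expr = _expr_matrix(rng.normal(size=(10, 12)))
        lab = make_labeling(np.repeat([1, 2, 3], 4))
        p1 = permutation_pvalues(expr, lab, B=99, seed=11)
        p2 = permutation_pvalues(expr, lab, B=99, seed=11)
        pd.testing.assert_series_equal(p1, p2)
        p3 = permutation_pvalues(expr, lab, B=99, seed=12)
        assert not p1.equals(p3)

    def test_seed_is_mandatory_and_b_validated(self):
        expr = _expr_matrix(np.zeros((2, 4)))
        lab = make_labeling([1, 1, 2, 2])
        with pytest.raises(DomainError):
            permutation_pvalues(expr, lab, B=0, seed=1)
        with pytest.raises(DomainError):
            permutation_pvalues(expr, lab, B=10)


class TestBHQvalues:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.5], [0.5]),
            ([1.0, 1.0], [1.0, 1.0]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ],
    )
    def test_step_up_examples(self, p, expected):
        np.testing.assert_allclose(bh_qvalues(p), expected)

    def test_out_of_domain_p_rejected(self):
        with pytest.raises(DomainError):
            bh_qvalues([0.0, 0.5])
        with pytest.raises(DomainError):
            bh_qvalues([0.5, 1.5])

    def test_matches_statsmodels_and_rejection_set(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 200))
            q = bh_qvalues(p)
            reject, q_sm, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_allclose(q, q_sm, rtol=1e-12)
            np.testing.assert_array_equal(q < 0.05, reject)

    def test_qvalues_dominate_pvalues_in_order(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(1e-6, 1, size=100)
        q = bh_qvalues(p)
        assert (q <= 1).all()
        # q preserves the p ranking
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestSelectMegs:
    def test_planted_perfect_genes_rank_first(self):
        rng = np.random.default_rng(8)
        levels = np.repeat([1, 2, 3, 4], 5)
        noise = rng.normal(size=(90, 20))
        planted = levels[None, :] * 10.0 + rng.normal(scale=0.01, size=(10, 20))
        expr = _expr_matrix(np.vstack([noise, planted]))
        lab = make_labeling(levels)
        res = select_megs(expr, lab, "ascending", B=99, seed=4)
        ranked = res.table.sort_values(["de_total", "gene"])["gene"].tolist()
        planted_ids = {f"g{i}" for i in range(91, 101)}
        assert set(ranked[:10]) == planted_ids
        assert (res.table.set_index("gene").loc[sorted(planted_ids), "de_total"] == 0).all()

    def test_pure_noise_yields_no_calls(self):
        rng = np.random.default_rng(9)
        expr = _expr_matrix(rng.normal(size=(100, 24)))
        lab = make_labeling(np.repeat([1, 2, 3, 4], 6))
        res = select_megs(expr, lab, "ascending", B=199, seed=10, alpha=0.05)
        assert res.n_significant(0.05) <= 2

    def test_empty_gene_set_gives_empty_results(self):
        sample_ids = [f"s{i}" for i in range(8)]
        expr = ExpressionMatrix(pd.DataFrame(np.empty((0, 8)), columns=sample_ids))
        lab = make_labeling(np.repeat([1, 2], 4), sample_ids=sample_ids)
        res = select_megs(expr, lab, B=19, seed=0)
        assert len(res.table) == 0

    def test_recovery_with_sufficient_permutation_depth(self, ac_like_dataset):
        """With B large enough that 1/(B+1) clears the BH bar, the planted
        monotone genes are recovered at q < 0.05 with few false calls."""
        from megselect import assign_risk_groups

        expr, clin, truth = ac_like_dataset
        labeling = assign_risk_groups(clin)
        called: set = set()
        for i, direction in enumerate(("ascending", "descending")):
            res = select_megs(expr, labeling, direction, B=999, seed=100 + i)
            called |= set(res.significant_genes)
        planted = set(truth.planted_genes)
        sensitivity = len(called & planted) / len(planted)
        fdr = len(called - planted) / max(1, len(called))
        assert sensitivity >= 0.9
        assert fdr <= 0.10

    def test_alpha_validated(self):
        expr = _expr_matrix(np.zeros((2, 4)))
        lab = make_labeling([1, 1, 2, 2])
        with pytest.raises(DomainError):
            select_megs(expr, lab, B=10, seed=1, alpha=1.1)
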