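import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cernet.rra import (
    aggregate,
    beta_scores,
    normalized_ranks,
    rho_score,
    select_robust,
)

from _oracles import order_stat_tail_mc


class TestNormalizedRanks:
    def test_rank_definition_and_missing(self):
        mat = normalized_ranks([["a", "b"], ["b"]], [10, 5])
        assert mat.at["a", 0] == pytest.approx(0.1)
        assert mat.at["b", 0] == pytest.approx(0.2)
        assert mat.at["b", 1] == pytest.approx(0.2)
        assert np.isnan(mat.at["a", 1])

    def test_full_list_last_item_rank_one(self):
        items = [f"x{i}" for i in range(7)]
        mat = normalized_ranks([items], [7])
        assert mat.at["x6", 0] == pytest.approx(1.0)

    def test_duplicate_within_list_errors(self):
        with pytest.raises(ValueError, match="duplicate"):
            normalized_ranks([["a", "a"]], [5])

    def test_universe_smaller_than_list_errors(self):
        with pytest.raises(ValueError, match="universe"):
            normalized_ranks([["a", "b", "c"]], [2])


class TestBetaScores:
    def test_single_list_is_uniform_cdf(self):
        assert beta_scores([0.3], 1) == pytest.approx([0.3])

    def test_closed_form_m2(self):
        beta = beta_scores([0.1, 0.2], 2)
        assert beta[0] == pytest.approx(1 - 0.9 ** 2, abs=1e-12)
        assert beta[1] == pytest.approx(0.2 ** 2, abs=1e-12)

    def test_all_ones_full_support(self):
        assert beta_scores([1.0, 1.0, 1.0], 3) == pytest.approx([1, 1, 1])

    def test_unsorted_errors(self):
        with pytest.raises(ValueError, match="sorted"):
            beta_scores([0.5, 0.2], 2)

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_exact_order_statistic_formula(self, ranks):
        """beta_k equals the exact incomplete-beta order-statistic CDF."""
        from scipy import stats as ss
        r = np.sort(np.asarray(ranks))
        m = len(r)
        beta = beta_scores(r, m)
        for k in range(1, m + 1):
            # P(U_(k) <= x) = I_x(k, m - k + 1), the regularized
            # incomplete beta — an independent closed form
            expected = ss.beta.cdf(r[k - 1], k, m - k + 1)
            assert beta[k - 1] == pytest.approx(expected, abs=1e-10)

    def test_matches_monte_carlo_oracle(self, rng):
        r = np.array([0.15, 0.4, 0.7])
        beta = beta_scores(r, 3)
        n = 10_000
        emp = order_stat_tail_mc(r, 3, n, rng)
        se = np.sqrt(beta * (1 - beta) / n)
        assert (np.abs(emp - beta) < 3 * np.maximum(se, 1e-4)).all()


class TestRhoScore:
    def test_m2_hand_case(self):
        rho, score = rho_score([0.1, 0.2], 2)
        assert rho == pytest.approx(0.04, abs=1e-12)
        assert score == pytest.approx(0.08, abs=1e-12)

    def test_single_list_no_correction(self):
        assert rho_score([0.3], 1) == (pytest.approx(0.3), pytest.approx(0.3))

    def test_null_item_scores_one(self):
        _, score = rho_score([1.0] * 4, 4)
        assert score == 1.0

    @given(st.lists(st.floats(0.01, 0.99), min_size=2, max_size=5),
           st.integers(0, 4), st.floats(0.01, 0.3))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_score_monotone_in_rank_entries(self, ranks, pos, delta):
        """Improving (decreasing) any rank never worsens the score."""
        r = sorted(ranks)
        m = len(r)
        pos = pos % m
        better = sorted(r[:pos] + [max(1e-6, r[pos] - delta)] + r[pos + 1:])
        _, s_before = rho_score(r, m)
        _, s_after = rho_score(better, m)
        assert s_after <= s_before + 1e-12


class TestAggregate:
    def test_top_in_all_five_lists_closed_form(self):
        """Item ranked first in all 5 lists of universe 1000: the minimum
        over k of the binomial tails is attained at k=5, giving
        rho = 0.001^5 and score = 5 * rho (this matches the magnitude the
        published meta-analysis reports for its top gene)."""
        from scipy import stats as ss
        lists = [["star"] + [f"f{j}_{i}" for i in range(9)] for j in range(5)]
        out = aggregate(lists, [1000] * 5)
        r = 1 / 1000
        tails = [ss.binom.sf(k - 1, 5, r) for k in range(1, 6)]
        assert min(tails) == pytest.approx(r ** 5, rel=1e-9)
        assert out.loc["star", "rho"] == pytest.approx(min(tails), rel=1e-9)
        assert out.loc["star", "score"] == pytest.approx(5 * r ** 5, rel=1e-9)

    def test_item_in_no_list_absent(self):
        out = aggregate([["a"], ["a"]], [10, 10])
        assert list(out.index) == ["a"]

    def test_missing_entries_get_worst_rank(self):
        out = aggregate([["a", "b"], ["b"]], [10, 10])
        rho_a, score_a = rho_score([0.1, 1.0], 2)
        assert out.loc["a", "score"] == pytest.approx(score_a, abs=1e-12)

    def test_sorted_by_score_then_item(self):
        out = aggregate([["a", "b", "c"], ["c", "b", "a"]], [10, 10])
        assert list(out.index) == sorted(
            out.index, key=lambda i: (out.loc[i, "score"], i))

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            aggregate([], [])

    def test_mean_lfc_over_measured_datasets(self):
        lfc = pd.DataFrame({0: {"a": 1.0, "b": 2.0}, 1: {"a": 3.0}})
        out = aggregate([["a", "b"], ["a"]], [10, 10], lfc)
        assert out.loc["a", "mean_lfc"] == pytest.approx(2.0)
        assert out.loc["b", "mean_lfc"] == pytest.approx(2.0)

    def test_bonferroni_validity_permutation_null(self, rng):
        """Under random permutations, P(score < alpha) <= alpha + 3 SE."""
        n_items, m, n_perm = 20, 3, 10_000
        items = np.arange(n_items)
        hits = {0.01: 0, 0.05: 0}
        for _ in range(n_perm):
            ranks = np.empty(m)
            for j in range(m):
                perm = rng.permutation(n_items)
                ranks[j] = (np.where(perm == 0)[0][0] + 1) / n_items
            _, score = rho_score(np.sort(ranks), m)
            for alpha in hits:
                hits[alpha] += score < alpha
        for alpha, h in hits.items():
            se = math.sqrt(alpha * (1 - alpha) / n_perm)
            assert h / n_perm <= alpha + 3 * se

    def test_extra_all_missing_list_changes_only_by_correction(self):
        """Appending a list ranking none of the items shifts each score by
        no more than the recomputed m and extra r=1 entry predict."""
        lists = [["a", "b", "c"], ["b", "a"]]
        base = aggregate(lists, [10, 10])
        extended = aggregate(lists + [["zz"]], [10, 10, 10])
        for item in ["a", "b", "c"]:
            mat = normalized_ranks(lists, [10, 10])
            r = np.sort(np.nan_to_num(mat.loc[item].to_numpy(), nan=1.0))
            _, direct = rho_score(np.sort(np.append(r, 1.0)), 3)
            assert extended.loc[item, "score"] == pytest.approx(direct,
                                                                abs=1e-12)


class TestSelectRobust:
    def _table(self, rows):
        return pd.DataFrame(rows).set_index("item")

    def test_passing_item_kept_with_direction(self):
        up = self._table([{"item": "g", "rho": 0.02, "score": 0.04,
                           "mean_lfc": 0.6}])
        down = self._table([{"item": "h", "rho": 0.01, "score": 0.03,
                             "mean_lfc": -0.9}])
        out = select_robust(up, down)
        assert out.loc["g", "direction"] == "up"
        assert out.loc["h", "direction"] == "down"

    def test_lfc_gate_excludes(self):
        up = self._table([{"item": "g", "rho": 0.02, "score": 0.04,
                           "mean_lfc": 0.4}])
        down = up.iloc[:0]
        assert len(select_robust(up, down)) == 0

    def test_direction_conflict_errors(self):
        up = self._table([{"item": "g", "rho": 0.01, "score": 0.02,
                           "mean_lfc": 0.8}])
        down = self._table([{"item": "g", "rho": 0.01, "score": 0.02,
                             "mean_lfc": -0.8}])
        with pytest.raises(ValueError, match="both directions"):
            select_robust(up, down)
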