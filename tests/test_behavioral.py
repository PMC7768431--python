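"""Divergent-thinking scoring, agreement, correlations and group contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fluencynet.behavioral import (
    compare_groups,
    correlate_indices,
    icc_consistency,
    median_split,
    score_aut,
    score_aut_table,
)
from fluencynet.exceptions import ValidationError


def _ideas(rows):
    return pd.DataFrame(rows, columns=["idea", "rater1", "rater2", "category"])


class TestScoreAut:
    def test_direct_formula(self):
        ideas = _ideas([(f"i{k}", 4, 4, f"c{k % 3}") for k in range(5)])
        s = score_aut(ideas, "P1")
        assert (s.fluency, s.flexibility) == (5, 3)
        assert s.creativity_sum == 20 and s.creativity_mean == 4 and s.odt == 7

    def test_single_idea_rater_average(self):
        s = score_aut(_ideas([("doorstop", 3, 5, "building")]), "P1")
        assert s.creativity_sum == 4 and s.odt == 5

    def test_no_ideas_is_degenerate_with_zero_odt(self):
        with pytest.warns(UserWarning, match="no scorable ideas"):
            s = score_aut(_ideas([]), "P9")
        assert s.odt == 0 and s.degenerate and np.isnan(s.creativity_mean)

    def test_redundant_ideas_counted_once(self):
        s = score_aut(_ideas([("x", 2, 2, "a"), ("x", 2, 2, "a"), ("y", 3, 3, "b")]))
        assert s.fluency == 2

    def test_odt_invariant_to_idea_order(self):
        rows = [(f"i{k}", 1 + k % 5, 5 - k % 5, f"c{k % 4}") for k in range(8)]
        a = score_aut(_ideas(rows))
        b = score_aut(_ideas(rows[::-1]))
        assert a.odt == pytest.approx(b.odt)

    def test_rating_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            score_aut(_ideas([("x", 0, 3, "a")]))

    def test_table_scoring_groups_by_participant(self):
        long = pd.DataFrame({
            "participant": ["a", "a", "b"],
            "idea": ["i1", "i2", "i1"],
            "rater1": [2, 4, 5],
            "rater2": [2, 4, 5],
            "category": ["c1", "c2", "c1"],
        })
        table = score_aut_table(long)
        assert table.loc["a", "fluency"] == 2 and table.loc["b", "odt"] == 6


class TestICC:
    def test_identical_raters_give_one(self):
        x = np.array([1.0, 2, 3, 4, 5])
        single, average = icc_consistency(x, x)
        assert single == pytest.approx(1.0) and average == pytest.approx(1.0)

    def test_consistency_ignores_additive_shift(self):
        x = np.array([1.0, 2, 3, 4, 5])
        single, average = icc_consistency(x, x + 2.0)
        assert single == pytest.approx(1.0) and average == pytest.approx(1.0)

    def test_matches_variance_components_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        truth = rng.normal(0, 1.0, 20)
        r1 = truth + rng.normal(0, 1.0, 20)
        r2 = truth + rng.normal(0, 1.0, 20)
        single, average = icc_consistency(r1, r2)
        long = pd.DataFrame({
            "targets": np.tile(np.arange(20), 2),
            "raters": np.repeat(["r1", "r2"], 20),
            "scores": np.concatenate([r1, r2]),
        })
        icc = pingouin.intraclass_corr(long, targets="targets", raters="raters",
                                       ratings="scores").set_index("Type")
        assert single == pytest.approx(icc.loc["ICC(C,1)", "ICC"], abs=1e-9)
        assert average == pytest.approx(icc.loc["ICC(C,k)", "ICC"], abs=1e-9)

    def test_zero_item_variance_is_nan(self):
        with pytest.warns(UserWarning, match="ICC undefined"):
            single, average = icc_consistency(np.ones(5), np.ones(5))
        assert np.isnan(single) and np.isnan(average)


class TestCorrelateIndices:
    def test_monotone_identical_and_reversed(self):
        scores = pd.DataFrame({
            "flexibility": [1, 2, 3, 4, 5],
            "fluency": [2, 4, 6, 8, 10],
            "creativity_sum": [10, 8, 6, 4, 2],
            "odt": [1.5, 2.5, 3.5, 4.5, 5.5],
        })
        rho, _ = correlate_indices(scores)
        assert rho.loc["flexibility", "fluency"] == pytest.approx(1.0)
        assert rho.loc["flexibility", "creativity_sum"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=58)
        scores = pd.DataFrame({
            "flexibility": np.exp(base + rng.normal(0, 0.5, 58)),
            "fluency": np.exp(base + rng.normal(0, 0.5, 58)),
            "creativity_sum": np.exp(base + rng.normal(0, 0.5, 58)),
            "odt": base + rng.normal(0, 0.5, 58),
        })
        rho, _ = correlate_indices(scores)
        for a, b in [("flexibility", "fluency"), ("creativity_sum", "odt")]:
            ranks_a = stats.rankdata(np.log(scores[a]) if a != "odt" else scores[a])
            ranks_b = stats.rankdata(np.log(scores[b]) if b != "odt" else scores[b])
            expected = np.corrcoef(ranks_a, ranks_b)[0, 1]
            assert rho.loc[a, b] == pytest.approx(expected, abs=1e-12)

    def test_zeros_fall_back_to_log1p_with_warning(self):
        scores = pd.DataFrame({
            "flexibility": [0, 1, 2, 3, 4],
            "fluency": [1, 2, 3, 4, 5],
            "creativity_sum": [2, 3, 4, 5, 6],
            "odt": [1, 2, 3, 4, 5],
        })
        with pytest.warns(UserWarning, match="log\\(x\\+1\\)"):
            rho, _ = correlate_indices(scores)
        assert rho.loc["flexibility", "fluency"] == pytest.approx(1.0)


class TestMedianSplit:
    def test_even_split(self):
        scores = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        assignment = median_split(scores)
        assert set(assignment.group("low")) == {"a", "b"}
        assert set(assignment.group("high")) == {"c", "d"}

    def test_ties_broken_by_id_order_with_warning(self):
        scores = pd.Series([5.0, 5, 5, 5], index=list("dcba"))
        with pytest.warns(UserWarning, match="tied"):
            assignment = median_split(scores)
        assert set(assignment.group("low")) == {"a", "b"}

    def test_odd_n_middle_goes_low(self):
        scores = pd.Series([1.0, 2, 3], index=list("abc"))
        with pytest.warns(UserWarning, match="odd"):
            assignment = median_split(scores)
        assert set(assignment.group("low")) == {"a", "b"}

    def test_study_split_is_equal_sized_and_deterministic(self, study):
        assignment = median_split(study.scores["odt"], variable="odt")
        assert len(assignment.group("low")) == len(assignment.group("high")) == 29
        again = median_split(study.scores["odt"], variable="odt")
        assert assignment.labels == again.labels

    def test_split_recovers_generating_groups(self, study):
        assignment = median_split(study.scores["odt"])
        truth = study.scores["group_true"]
        assert all(assignment.labels[p] == truth[p] for p in truth.index)


class TestCompareGroups:
    def _assignment(self, ids_low, ids_high):
        from fluencynet.behavioral import GroupAssignment
        labels = {p: "low" for p in ids_low} | {p: "high" for p in ids_high}
        return GroupAssignment(labels=labels, variable="x", threshold=0.0)

    def test_identical_means_give_zero(self):
        values = pd.Series([1.0, 2, 1, 2], index=list("abcd"))
        t, p, d = compare_groups(values, self._assignment("ab", "cd"))
        assert t == pytest.approx(0) and d == pytest.approx(0)

    def test_effect_size_recovers_unit_shift(self):
        rng = np.random.default_rng(123)
        low = rng.normal(0, 1, 1000)
        high = rng.normal(1, 1, 1000)
        values = pd.Series(np.concatenate([low, high]),
                           index=[f"l{i}" for i in range(1000)] + [f"h{i}" for i in range(1000)])
        t, p, d = compare_groups(
            values, self._assignment([f"l{i}" for i in range(1000)],
                                     [f"h{i}" for i in range(1000)]))
        # d estimates 1 with SE ~ sqrt(2/n); allow 3 SE
        assert abs(d - 1.0) < 3 * np.sqrt(2 / 1000)
        assert p < 1e-10

    def test_swapped_labels_negate_t_and_preserve_d(self):
        values = pd.Series([1.0, 2, 4, 5], index=list("abcd"))
        t1, _, d1 = compare_groups(values, self._assignment("ab", "cd"))
        t2, _, d2 = compare_groups(values, self._assignment("cd", "ab"))
        assert t1 == pytest.approx(-t2) and abs(d1) == pytest.approx(abs(d2))

    def test_zero_pooled_variance_flagged(self):
        values = pd.Series([0.0, 0, 1, 1], index=list("abcd"))
        with pytest.warns(UserWarning, match="infinite"):
            t, p, d = compare_groups(values, self._assignment("ab", "cd"))
        assert np.isinf(t)
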