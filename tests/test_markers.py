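"""Single-marker statistics: the three tests, BH, AUC, folds, filters, Venn."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mirblood.config import FilterCriteria
from mirblood.markers import (
    UndefinedFoldError,
    apply_marker_filters,
    bh_adjust,
    estimate_variance_prior,
    fold_quotient,
    format_fold,
    moderated_t_test,
    roc_auc,
    significance_sets,
    t_test,
    wmw_test,
)


class TestTTest:
    def test_identical_groups_give_p_one(self):
        assert t_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_closed_form_example(self):
        # t = 2/sqrt(2/3), df = 4 -> p ~ 0.0705
        expected = 2 * stats.t.sf(2 / np.sqrt(2 / 3), df=4)
        assert t_test([1, 2, 3], [3, 4, 5]) == pytest.approx(expected, rel=1e-10)
        assert t_test([1, 2, 3], [3, 4, 5]) == pytest.approx(0.0705, abs=5e-4)

    def test_two_tailed_symmetry(self):
        assert t_test([1, 2, 3], [3, 4, 5]) == t_test([3, 4, 5], [1, 2, 3])

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            t_test([1], [2, 3])

    def test_zero_variance_equal_means(self):
        assert t_test([5, 5, 5], [5, 5, 5]) == 1.0


class TestWmwTest:
    def test_exact_enumeration_example(self):
        # U = 0; 1 of C(4,2)=6 arrangements per tail
        assert wmw_test([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_groups(self):
        assert wmw_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_rank_invariance_under_shift(self):
        a, b = [1.0, 5.0, 9.0], [2.0, 3.0, 11.0]
        shifted = wmw_test([x + 100 for x in a], [x + 100 for x in b])
        assert wmw_test(a, b) == shifted

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wmw_test([], [1.0])


class TestModeratedT:
    @staticmethod
    def _heteroscedastic_fixture():
        # must match the frozen external-oracle fixture below
        rng = np.random.default_rng(123)
        sd = np.sqrt(0.5 * 4 / rng.chisquare(4, size=40))
        X = rng.normal(0, 1, size=(40, 12)) * sd[:, None]
        X[:5, 6:] += np.linspace(0.5, 2.5, 5)[:, None]
        return X, np.array([0] * 6 + [1] * 6)

    # Reference p-values from an independent empirical-Bayes linear-model
    # implementation run on the exact fixture above (two-group design).
    _ORACLE_P = np.array([
        0.399197171498, 0.00293253928922, 0.0819087465163, 2.45371078081e-06,
        0.000142285863209, 0.805098111392, 0.758050638593, 0.809101672982,
        0.267298240633, 0.134982408003, 0.799389963667, 0.658088779846,
        0.25418233752, 0.718206659107, 0.452717975364, 0.340905182339,
        0.733070745624, 0.272612307575, 0.408758549093, 0.0853769925727,
        0.126776110237, 0.894698420942, 0.0733343203793, 0.0812200799438,
        0.553504060754, 0.77954974879, 0.518853678174, 0.409157307452,
        0.0864055119322, 0.537605941663, 0.86915683095, 0.791148918864,
        0.50775908058, 0.961349638706, 0.436927503289, 0.323924661773,
        0.820291516383, 0.577279487041, 0.689615029163, 0.0982171148351,
    ])

    def test_matches_independent_oracle(self):
        X, labels = self._heteroscedastic_fixture()
        p = moderated_t_test(X, labels)
        np.testing.assert_allclose(p, self._ORACLE_P, rtol=1e-6)

    def test_estimated_prior_matches_oracle(self):
        X, labels = self._heteroscedastic_fixture()
        m0 = X[:, labels == 0].mean(axis=1, keepdims=True)
        m1 = X[:, labels == 1].mean(axis=1, keepdims=True)
        rss = ((X[:, labels == 0] - m0) ** 2).sum(1) + ((X[:, labels == 1] - m1) ** 2).sum(1)
        d0, s0_sq = estimate_variance_prior(rss / 10, 10)
        assert d0 == pytest.approx(4.8569, abs=1e-3)
        assert s0_sq == pytest.approx(0.4461741, rel=1e-5)

    def test_zero_prior_df_recovers_ordinary_t(self):
        X, labels = self._heteroscedastic_fixture()
        p = moderated_t_test(X, labels, prior_df=0.0)
        expected = stats.ttest_ind(
            X[:, labels == 0], X[:, labels == 1], axis=1, equal_var=True
        ).pvalue
        np.testing.assert_allclose(p, expected, rtol=1e-10)

    def test_infinite_prior_df_uses_common_variance(self):
        X, labels = self._heteroscedastic_fixture()
        p = moderated_t_test(X, labels, prior_df=np.inf)
        # a common variance makes the statistic proportional to the effect
        effect = np.abs(X[:, labels == 1].mean(1) - X[:, labels == 0].mean(1))
        order_p = np.argsort(p)
        order_e = np.argsort(effect)[::-1]
        np.testing.assert_array_equal(order_p, order_e)

    def test_all_zero_variance_rejected(self):
        X = np.ones((12, 8))
        with pytest.raises(ValueError, match="zero residual variance"):
            moderated_t_test(X, [0, 0, 0, 0, 1, 1, 1, 1])


class TestBhAdjust:
    def test_single_p(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_executed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.001, 0.01, 0.03, 0.04]), [0.004, 0.02, 0.04, 0.04]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_properties(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0)
        # monotone in raw ranks
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        # order invariance
        perm = np.random.default_rng(0).permutation(len(pvals))
        np.testing.assert_allclose(adj[perm], bh_adjust(np.asarray(pvals)[perm]))


def _auc_bruteforce(cases, controls):
    wins = ties = 0
    for c in cases:
        for n in controls:
            wins += c > n
            ties += c == n
    a = (wins + 0.5 * ties) / (len(cases) * len(controls))
    return max(a, 1 - a)


class TestRocAuc:
    @pytest.mark.parametrize(
        "cases, controls, expected",
        [
            ([3, 5, 7], [1, 2, 6], 7 / 9),
            ([5, 6, 7], [1, 2, 3], 1.0),  # perfect separation
            ([2, 2], [2, 1], 0.75),  # half-weight ties
        ],
    )
    def test_pair_counting_examples(self, cases, controls, expected):
        values = np.array(cases + controls, dtype=float)
        labels = np.array([1] * len(cases) + [0] * len(controls))
        assert roc_auc(values, labels, positive=1) == pytest.approx(expected)

    def test_symmetrization_reports_down_markers_near_one(self):
        values = np.array([1.0, 2.0, 3.0, 8.0, 9.0, 10.0])
        labels = np.array([1, 1, 1, 0, 0, 0])  # cases below controls
        assert roc_auc(values, labels, positive=1) == 1.0
        assert roc_auc(values, labels, positive=1, symmetrize=False) == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1.0, 2.0], [1, 1], positive=1)

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            n1, n0 = rng.integers(1, 9, size=2)
            cases = rng.integers(0, 6, size=n1).astype(float)
            controls = rng.integers(0, 6, size=n0).astype(float)
            values = np.concatenate([cases, controls])
            labels = np.array([1] * n1 + [0] * n0)
            assert roc_auc(values, labels, positive=1) == pytest.approx(
                _auc_bruteforce(cases, controls)
            )


class TestFoldQuotient:
    @pytest.mark.parametrize(
        "case, control, printed",
        [(206.5, 26.2, 7.9), (189.7, 633.3, 0.3), (105.3, 2.0, 53.0)],
    )
    def test_published_rounding(self, case, control, printed):
        assert format_fold(fold_quotient(case, control)) == printed

    def test_identity(self):
        assert fold_quotient(123.4, 123.4) == 1.0

    def test_zero_control_flagged(self):
        with pytest.raises(UndefinedFoldError):
            fold_quotient(10.0, 0.0)


class TestSignificanceSets:
    def _adj(self, mapping):
        index = pd.Index(sorted({f for s in mapping.values() for f in s} | {"zz"}))
        return {
            name: pd.Series(
                [0.0005 if f in sig else 0.5 for f in index], index=index
            )
            for name, sig in mapping.items()
        }

    def test_three_identical_sets(self):
        adj = self._adj({"t": {"a", "b"}, "w": {"a", "b"}, "l": {"a", "b"}})
        _, venn = significance_sets(adj)
        assert venn.abc == 2 and venn.union_total == 2

    def test_enumerated_partition(self):
        adj = self._adj({"t": {"1", "2", "3"}, "w": {"2", "3", "4"}, "l": {"3", "4", "5"}})
        sets, venn = significance_sets(adj)
        assert venn.abc == 1  # {3}
        assert (venn.only_a, venn.only_b, venn.only_c) == (1, 0, 1)
        assert (venn.ab_only, venn.bc_only, venn.ac_only) == (1, 1, 0)
        assert venn.union_total == 5
        assert venn.union_total == len(sets["t"] | sets["w"] | sets["l"])

    def test_misaligned_ids_rejected(self):
        adj = self._adj({"t": {"a"}, "w": {"a"}, "l": {"a"}})
        adj["l"] = adj["l"].iloc[:-1]
        with pytest.raises(ValueError, match="misaligned"):
            significance_sets(adj)


class TestMarkerFilters:
    def _record(self, median_case, median_control, adj=1e-5, auc=0.9):
        return pd.DataFrame(
            {
                "median_case": [median_case],
                "median_control": [median_control],
                "fold_change": [median_case / median_control],
                "adj_t": [adj],
                "adj_wmw": [adj],
                "adj_limma": [adj],
                "auc": [auc],
            },
            index=["f0"],
        )

    def test_below_both_thresholds_excluded(self):
        assert apply_marker_filters(self._record(90.0, 80.0)).empty

    def test_boundary_values_retained(self):
        kept = apply_marker_filters(self._record(100.0, 50.0))  # fold exactly 2
        assert len(kept) == 1

    def test_one_low_median_is_not_excluded(self):
        # expressed in one group only: the "both medians below" reading keeps it
        kept = apply_marker_filters(self._record(105.3, 2.0))
        assert len(kept) == 1

    def test_nonsignificant_excluded(self):
        assert apply_marker_filters(self._record(400.0, 100.0, adj=0.01)).empty

    def test_sorted_by_auc_descending(self):
        records = pd.concat(
            [self._record(400, 100.0, auc=0.8), self._record(500, 100.0, auc=0.95)]
        )
        records.index = ["low", "high"]
        assert list(apply_marker_filters(records).index) == ["high", "low"]


def test_null_cohort_yields_no_markers(null_cohort):
    """No planted effect: the stringent filters keep nothing."""
    from mirblood.markers import build_marker_table

    m, ann, _ = null_cohort
    table = build_marker_table(m, ann)
    assert apply_marker_filters(table, FilterCriteria()).empty
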