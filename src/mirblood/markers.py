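"""Per-miRNA differential statistics and the stringency-filtered marker table.

Three hypothesis tests per feature (unpaired two-tailed t, Wilcoxon
Mann-Whitney, and an empirical-Bayes moderated t), Benjamini-Hochberg
adjustment per test, a threshold-sweep ROC AUC symmetrized to [0.5, 1],
group-median fold quotients, and the stringency filters (all three adjusted
p below alpha, at least ``min_fold``-fold in either direction, and at least
one group median above ``min_median``).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .config import FilterCriteria
from .preprocess import group_medians

MARKER_COLUMNS = [
    "median_case",
    "median_control",
    "fold_change",
    "p_t",
    "p_wmw",
    "p_limma",
    "adj_t",
    "adj_wmw",
    "adj_limma",
    "auc",
]


class UndefinedFoldError(ZeroDivisionError):
    """Fold quotient against a zero control median."""


def t_test(case, control, equal_var: bool = False) -> float:
    """Two-tailed unpaired two-sample t-test p-value (Welch by default).

    Two groups with zero variance and equal means give p = 1 (no evidence of
    a difference rather than an undefined statistic).
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size < 2 or control.size < 2:
        raise ValueError("t-test needs at least 2 values per group")
    if not (np.isfinite(case).all() and np.isfinite(control).all()):
        raise ValueError("t-test inputs must be finite")
    if case.std() == 0.0 and control.std() == 0.0:
        return 1.0 if case.mean() == control.mean() else 0.0
    return float(stats.ttest_ind(case, control, equal_var=equal_var).pvalue)


def wmw_test(case, control) -> float:
    """Two-tailed Wilcoxon Mann-Whitney p-value.

    Exact enumeration when both groups have <= 12 observations and no ties;
    otherwise the tie-corrected normal approximation.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("WMW test needs non-empty groups")
    pooled = np.concatenate([case, control])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (case.size <= 12 and control.size <= 12 and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(case, control, alternative="two-sided", method=method).pvalue
    )


def _invert_trigamma(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y  # standard starting value
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match (prior df d0, prior variance s0^2) on log residual variances.

    Under the hierarchical model the log variances ``z = log s^2`` follow a
    shifted log-F distribution; matching the mean and variance of ``z``
    through digamma/trigamma identities yields the prior. An observed spread
    no larger than the sampling spread gives an infinite prior df (full
    shrinkage to a common variance).
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2 > 0
    if not positive.any():
        raise ValueError("all features have zero residual variance")
    z = np.log(s2[positive])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if e_var <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    else:
        d0 = 2.0 * _invert_trigamma(float(e_var))
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t_test(
    matrix: pd.DataFrame | np.ndarray,
    labels,
    prior_df: float | None = None,
) -> pd.Series | np.ndarray:
    """Empirical-Bayes moderated two-group t-test p-values per feature.

    Fits the two-group linear model per feature (rows of ``matrix``), shrinks
    the residual variances toward an estimated prior,
    ``s2_post = (d0*s0^2 + d*s2) / (d0 + d)``, and tests the group effect on
    ``d0 + d`` degrees of freedom. ``prior_df`` overrides the estimated d0
    (0 recovers the ordinary equal-variance t-test; ``inf`` tests every
    feature against the common prior variance).
    """
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    g1, g2 = (y == classes[0]), (y == classes[1])
    n1, n2 = int(g1.sum()), int(g2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    if X.shape[0] < 10 and prior_df is None:
        raise ValueError("need >= 10 features to estimate the variance prior")

    m1, m2 = X[:, g1].mean(axis=1), X[:, g2].mean(axis=1)
    rss = ((X[:, g1] - m1[:, None]) ** 2).sum(axis=1) + (
        (X[:, g2] - m2[:, None]) ** 2
    ).sum(axis=1)
    df_resid = n1 + n2 - 2
    s2 = rss / df_resid
    v = 1.0 / n1 + 1.0 / n2

    if prior_df is None:
        d0, s0_sq = estimate_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        s0_sq = estimate_variance_prior(s2, df_resid)[1] if d0 > 0 else 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
    # Information cannot exceed the summed residual df across features.
    df_total = min(d0 + df_resid, X.shape[0] * df_resid)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(s2_post * v)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(t), 1.0, p)
    if isinstance(matrix, pd.DataFrame):
        return pd.Series(p, index=matrix.index, name="p_limma")
    return p


def bh_adjust(pvalues) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = multipletests(arr, method="fdr_bh")[1]
    if isinstance(pvalues, pd.Series):
        return pd.Series(adjusted, index=pvalues.index, name=pvalues.name)
    return adjusted


def roc_auc(values, labels, positive, symmetrize: bool = True) -> float:
    """Threshold-sweep ROC AUC of one feature's intensities.

    Equivalent to the normalized Mann-Whitney U statistic: the fraction of
    (case, control) pairs where the case intensity is higher, counting ties
    half. ``symmetrize`` reports max(AUC, 1 - AUC) so down-regulated markers
    score near 1 as well (the marker-table convention).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(values)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)
    return float(max(auc, 1.0 - auc)) if symmetrize else float(auc)


def fold_quotient(median_case: float, median_control: float) -> float:
    """Ratio of group medians (case over control)."""
    if median_control <= 0:
        raise UndefinedFoldError(
            f"control median {median_control} gives an undefined fold quotient"
        )
    return float(median_case) / float(median_control)


def format_fold(fold: float) -> float:
    """Reporting convention: one decimal, integer once the ratio reaches 10."""
    if not np.isfinite(fold):
        return fold
    if fold >= 10:
        return float(np.floor(fold + 0.5))
    return float(np.floor(fold * 10.0 + 0.5) / 10.0)  # round half up


@dataclass(frozen=True)
class VennPartition:
    """Seven-region partition of three significant-feature sets A, B, C."""

    only_a: int
    only_b: int
    only_c: int
    ab_only: int
    ac_only: int
    bc_only: int
    abc: int

    @property
    def union_total(self) -> int:
        return (
            self.only_a + self.only_b + self.only_c
            + self.ab_only + self.ac_only + self.bc_only + self.abc
        )

    def to_dict(self) -> dict[str, int]:
        return {
            "only_a": self.only_a,
            "only_b": self.only_b,
            "only_c": self.only_c,
            "ab_only": self.ab_only,
            "ac_only": self.ac_only,
            "bc_only": self.bc_only,
            "abc": self.abc,
            "union_total": self.union_total,
        }


def significance_sets(
    adjusted: dict[str, pd.Series], alpha: float = 0.001
) -> tuple[dict[str, set], VennPartition]:
    """Per-test significant feature sets and their Venn partition.

    ``adjusted`` maps exactly three test names to BH-adjusted p-value series
    over one shared feature index; significance is adjusted p < alpha.
    """
    if len(adjusted) != 3:
        raise ValueError("significance_sets expects exactly three tests")
    names = list(adjusted)
    index = adjusted[names[0]].index
    for name in names[1:]:
        if not adjusted[name].index.equals(index):
            raise ValueError(f"feature ids of test '{name}' are misaligned")
    sets = {name: set(index[adjusted[name] < alpha]) for name in names}
    a, b, c = (sets[n] for n in names)
    venn = VennPartition(
        only_a=len(a - b - c),
        only_b=len(b - a - c),
        only_c=len(c - a - b),
        ab_only=len((a & b) - c),
        ac_only=len((a & c) - b),
        bc_only=len((b & c) - a),
        abc=len(a & b & c),
    )
    return sets, venn


def build_marker_table(
    m: pd.DataFrame,
    ann: pd.DataFrame,
    case_groups=("M", "N"),
    control_groups=("C",),
    equal_var: bool = False,
) -> pd.DataFrame:
    """Full per-miRNA marker table over a normalized expression matrix.

    Columns: group medians, fold quotient (NaN-flagged where the control
    median is zero), raw and BH-adjusted p-values of the three tests, and the
    symmetrized AUC. Features stay in matrix order; use
    :func:`apply_marker_filters` for the stringent subset sorted by AUC.
    """
    case_ids = ann.loc[ann["group"].isin(
        (case_groups,) if isinstance(case_groups, str) else tuple(case_groups)
    ), "sample_id"]
    ctrl_ids = ann.loc[ann["group"].isin(
        (control_groups,) if isinstance(control_groups, str) else tuple(control_groups)
    ), "sample_id"]
    case_m = m[list(case_ids)].to_numpy(dtype=float)
    ctrl_m = m[list(ctrl_ids)].to_numpy(dtype=float)

    median_case, median_control = group_medians(m, ann, case_groups, control_groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(
            median_control.to_numpy() > 0,
            median_case.to_numpy() / np.where(median_control.to_numpy() > 0,
                                              median_control.to_numpy(), 1.0),
            np.nan,
        )

    import warnings

    with warnings.catch_warnings():
        # near-constant features (detection floor) trip scipy's precision
        # warning; they legitimately get p ~ 1
        warnings.simplefilter("ignore", RuntimeWarning)
        p_t = stats.ttest_ind(case_m, ctrl_m, axis=1, equal_var=equal_var).pvalue
        p_wmw = stats.mannwhitneyu(
            case_m, ctrl_m, axis=1, alternative="two-sided", method="asymptotic"
        ).pvalue
    p_t = np.where(np.isnan(p_t), 1.0, p_t)
    p_wmw = np.where(np.isnan(p_wmw), 1.0, p_wmw)
    labels = np.concatenate([np.ones(case_m.shape[1]), np.zeros(ctrl_m.shape[1])])
    both = np.hstack([case_m, ctrl_m])
    p_limma = moderated_t_test(both, labels)

    ranks = stats.rankdata(both, axis=1)
    u = ranks[:, labels == 1].sum(axis=1) - case_m.shape[1] * (case_m.shape[1] + 1) / 2.0
    auc_raw = u / (case_m.shape[1] * ctrl_m.shape[1])
    auc = np.maximum(auc_raw, 1.0 - auc_raw)

    table = pd.DataFrame(
        {
            "median_case": median_case,
            "median_control": median_control,
            "fold_change": fold,
            "p_t": p_t,
            "p_wmw": p_wmw,
            "p_limma": p_limma,
            "adj_t": bh_adjust(p_t),
            "adj_wmw": bh_adjust(p_wmw),
            "adj_limma": bh_adjust(p_limma),
            "auc": auc,
        },
        index=m.index,
    )
    table.index.name = "miRNA"
    return table


def apply_marker_filters(
    records: pd.DataFrame, criteria: FilterCriteria | None = None
) -> pd.DataFrame:
    """Stringency filters on a marker table; survivors sorted by AUC descending.

    Keeps a feature iff all three adjusted p-values fall below ``alpha``, the
    fold quotient is >= ``min_fold`` or <= 1/``min_fold`` (boundaries
    inclusive), and the larger group median reaches ``min_median``
    (boundary inclusive).
    """
    criteria = criteria or FilterCriteria()
    criteria.validate()
    significant = (
        (records["adj_t"] < criteria.alpha)
        & (records["adj_wmw"] < criteria.alpha)
        & (records["adj_limma"] < criteria.alpha)
    )
    fold = records["fold_change"]
    regulated = (fold >= criteria.min_fold) | (fold <= 1.0 / criteria.min_fold)
    expressed = records[["median_case", "median_control"]].max(axis=1) >= criteria.min_median
    kept = records[significant & regulated.fillna(False) & expressed]
    return kept.sort_values("auc", ascending=False, kind="stable")
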