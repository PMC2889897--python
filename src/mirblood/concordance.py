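"""Cross-cohort and cross-platform concordance.

Two reproducibility checks: (i) fold quotients of the two melanoma arms
(test and validation) against the shared controls, correlated on the log
scale; (ii) microarray fold changes against qPCR ddCt fold changes on the
linear scale, as printed in the validation table of the screening study.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import QpcrPanel


@dataclass(frozen=True)
class FoldQuotientSet:
    """Per-feature fold quotients of one melanoma arm versus the controls.

    Carries the arm's own median intensities and the retention threshold so a
    pair of sets can apply the "median >= min_median in at least one arm"
    rule at comparison time.
    """

    label: str
    quotients: pd.Series  # fold quotient per feature (case median / control median)
    case_medians: pd.Series
    min_median: float


def per_set_fold_quotients(
    case_matrix: pd.DataFrame,
    control_matrix: pd.DataFrame,
    min_median: float = 50.0,
    label: str = "",
) -> FoldQuotientSet:
    """Fold quotients of one melanoma arm's medians versus the control medians.

    Features with a zero control median are dropped (no defined quotient);
    the ``min_median`` retention against the other arm happens in
    :func:`log_fold_correlation`.
    """
    if not case_matrix.index.equals(control_matrix.index):
        raise ValueError("case and control matrices must share a feature universe")
    case_med = case_matrix.median(axis=1)
    ctrl_med = control_matrix.median(axis=1)
    defined = ctrl_med > 0
    if not defined.any():
        raise ValueError("no feature has a positive control median")
    quotients = case_med[defined] / ctrl_med[defined]
    return FoldQuotientSet(
        label=label,
        quotients=quotients,
        case_medians=case_med[defined],
        min_median=min_median,
    )


def log_fold_correlation(a: FoldQuotientSet, b: FoldQuotientSet) -> float:
    """Pearson correlation of log fold quotients over the retained intersection.

    A feature is retained when its median intensity reaches the threshold in
    at least one of the two melanoma arms.
    """
    shared = a.quotients.index.intersection(b.quotients.index)
    keep = shared[
        (a.case_medians[shared] >= a.min_median)
        | (b.case_medians[shared] >= b.min_median)
    ]
    if len(keep) < 3:
        raise ValueError(f"only {len(keep)} shared retained features; need >= 3")
    la = np.log(a.quotients[keep].to_numpy(dtype=float))
    lb = np.log(b.quotients[keep].to_numpy(dtype=float))
    return float(stats.pearsonr(la, lb)[0])


def ddct_fold_change(
    panel: QpcrPanel, case_group: str = "M", control_group: str = "C"
) -> pd.Series:
    """Relative fold changes 2^-ddCt per miRNA against the endogenous control.

    dCt = Ct(miRNA) - Ct(endogenous control) per sample; ddCt is the case
    minus control difference of group mean dCt; fold change = 2^-ddCt.
    miRNAs with missing Ct values are excluded with a warning.
    """
    groups = panel.samples.set_index("sample_id")["group"]
    ct = panel.ct
    if panel.control_id not in ct.columns or ct[panel.control_id].isna().any():
        raise ValueError("every sample needs an endogenous-control Ct")
    case_ids = groups.index[groups == case_group]
    ctrl_ids = groups.index[groups == control_group]
    if len(case_ids) == 0 or len(ctrl_ids) == 0:
        raise ValueError("both groups must be present in the panel")
    folds = {}
    for mirna in panel.mirna_ids:
        col = ct[mirna]
        if col.isna().any():
            warnings.warn(f"excluding {mirna}: missing Ct values", stacklevel=2)
            continue
        dct = col - ct[panel.control_id]
        ddct = dct[case_ids].mean() - dct[ctrl_ids].mean()
        folds[mirna] = 2.0 ** (-ddct)
    return pd.Series(folds, name="qpcr_fold_change")


def platform_correlation(qpcr_folds: pd.Series, array_folds: pd.Series) -> float:
    """Pearson correlation between qPCR and microarray fold changes.

    Computed on the linear fold-change scale over the paired features
    (the convention of the printed validation table; the test/validation
    comparison uses the log scale instead).
    """
    shared = qpcr_folds.index.intersection(array_folds.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} paired features; need >= 3")
    x = qpcr_folds[shared].to_numpy(dtype=float)
    y = array_folds[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("a fold-change vector is constant; correlation undefined")
    return float(stats.pearsonr(x, y)[0])
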