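"""Probe-level preprocessing: replicate summarization and quantile normalization.

The normalized expression matrix is a pandas DataFrame with features as rows
and samples as columns. Provenance flags live in ``DataFrame.attrs``
(``background_subtracted``, ``quantile_normalized``).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import ProbeLevelData


def summarize_replicates(data: ProbeLevelData) -> pd.DataFrame:
    """Median over replicate spots of background-subtracted intensity.

    Per cell: median over replicates of (intensity - background), clamped at
    zero. Replicate order is irrelevant by construction of the median.
    """
    if data.n_replicates < 1:
        raise ValueError("need at least one replicate per cell")
    diff = data.intensity - data.background
    values = np.clip(np.median(diff, axis=2), 0.0, None)
    m = pd.DataFrame(
        values,
        index=pd.Index(data.feature_ids, name="miRNA"),
        columns=list(data.sample_ids),
    )
    m.attrs["background_subtracted"] = True
    m.attrs["quantile_normalized"] = False
    return m


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common mean-quantile distribution.

    The reference distribution is the across-column mean of the sorted
    columns; each column's values are replaced by the reference value at
    their rank, with ties within a column receiving the mean of the tied
    reference values. Afterwards every column's sorted vector is identical.
    """
    if m.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    X = m.to_numpy(dtype=float)
    order = np.argsort(X, axis=0, kind="stable")
    ref = np.take_along_axis(X, order, axis=0).mean(axis=1)

    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = np.empty(X.shape[0])
        col[order[:, j]] = ref
        # ties within the column share the mean of their reference values
        out[:, j] = pd.Series(col).groupby(X[:, j]).transform("mean").to_numpy()
    normalized = pd.DataFrame(out, index=m.index, columns=m.columns)
    normalized.attrs = dict(m.attrs)
    normalized.attrs["quantile_normalized"] = True
    return normalized


def preprocess(data: ProbeLevelData) -> pd.DataFrame:
    """Replicate medians of background-subtracted spots, then quantile normalization."""
    return quantile_normalize(summarize_replicates(data))


def _resolve_groups(ann: pd.DataFrame, groups) -> pd.Index:
    labels = (groups,) if isinstance(groups, str) else tuple(groups)
    known = set(ann["group"])
    unknown = set(labels) - known
    if unknown:
        raise KeyError(f"unknown group label(s): {sorted(unknown)}")
    samples = ann.loc[ann["group"].isin(labels), "sample_id"]
    if samples.empty:
        raise ValueError(f"no samples in group(s) {labels}")
    return pd.Index(samples)


def group_medians(
    m: pd.DataFrame,
    ann: pd.DataFrame,
    case_groups=("M", "N"),
    control_groups=("C",),
) -> tuple[pd.Series, pd.Series]:
    """Per-feature medians over the case and control sample groups.

    Group arguments may be a single label or a sequence of labels to pool
    (the melanoma test and validation arms are pooled by default).
    """
    case = m[_resolve_groups(ann, case_groups)].median(axis=1)
    control = m[_resolve_groups(ann, control_groups)].median(axis=1)
    case.name, control.name = "median_case", "median_control"
    return case, control
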