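"""Supervised signature discovery with leak-free filter feature selection.

The procedure mirrors the screening design: repeated stratified k-fold
cross-validation of a kernel SVM, where inside every fold the features are
re-ranked by a two-sample t-test computed on the training split only, the
top-``s`` features are kept for a grid of subset sizes ``s``, and the kernel
and cost parameter are chosen by a nested CV on the training split. Permuted
class labels provide the no-signal accuracy distribution.
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import CvConfig, log_spaced_subset_sizes, reseed

_PROB_EPS = 1e-12


def _svm(kernel: str, cost: float, config: CvConfig, **kwargs) -> Pipeline:
    """Feature-standardized SVM (the convention of the reference SVM library:
    intensities span orders of magnitude, so the kernel needs unit-scale
    inputs). The scaler is always fit on training data only."""
    return Pipeline([
        ("scale", StandardScaler()),
        ("svc", SVC(kernel=config.sklearn_kernel(kernel), C=cost, gamma="scale", **kwargs)),
    ])


def _welch_pvalues(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Vectorized Welch t-test p-values per feature (rows)."""
    with warnings.catch_warnings():
        # near-constant features (detection floor) trip scipy's precision
        # warning; they legitimately get p ~ 1
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(case, control, axis=1, equal_var=False).pvalue
    return np.where(np.isnan(p), 1.0, p)


def rank_features_ttest(m: pd.DataFrame, labels) -> list[str]:
    """Feature ids ordered by ascending t-test p-value on the given samples.

    ``labels`` is a boolean/binary vector over the matrix columns; both
    classes must be present. Ties are broken deterministically by feature id.
    """
    y = np.asarray(labels).astype(bool)
    if y.all() or (~y).all():
        raise ValueError("training split must contain both classes")
    X = m.to_numpy(dtype=float)
    p = _welch_pvalues(X[:, y], X[:, ~y])
    order = sorted(range(len(p)), key=lambda i: (p[i], m.index[i]))
    return [m.index[i] for i in order]


@dataclass(frozen=True)
class CvResult:
    """Aggregated repeated-CV rates over the subset-size grid."""

    per_repetition: pd.DataFrame  # rep, subset_size, accuracy, sensitivity, specificity
    summary: pd.DataFrame  # per subset_size: means and percentile 95% CIs
    best_size: int
    signature: tuple[str, ...]
    selection_frequency: dict[str, float]  # at best_size, over reps x folds

    def rates_at_best(self) -> pd.Series:
        return self.summary.loc[self.best_size]


@dataclass(frozen=True)
class PermutationResult:
    """Null rates from re-running the CV machinery on permuted labels."""

    per_permutation: pd.DataFrame  # permutation, accuracy, sensitivity, specificity
    quantiles: pd.DataFrame

    @property
    def mean_accuracy(self) -> float:
        return float(self.per_permutation["accuracy"].mean())


def _choose_model(
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: CvConfig,
    seed: int,
) -> tuple[str, float]:
    """Pick (kernel, cost) by stratified CV on the training split only."""
    grid = [(k, c) for k in config.kernels for c in config.cost_grid]
    if len(grid) == 1:
        return grid[0]
    n_inner = min(config.inner_folds, int(np.bincount(y_train.astype(int)).min()))
    if n_inner < 2:
        return grid[0]
    inner = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=seed)
    splits = list(inner.split(X_train, y_train))
    best, best_acc = grid[0], -1.0
    for kernel, cost in grid:
        hits = total = 0
        for tr, te in splits:
            clf = _svm(kernel, cost, config)
            clf.fit(X_train[tr], y_train[tr])
            hits += int((clf.predict(X_train[te]) == y_train[te]).sum())
            total += len(te)
        acc = hits / total
        if acc > best_acc:
            best, best_acc = (kernel, cost), acc
    return best


def _rates(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    pos, neg = y_true == 1, y_true == 0
    sens = float((y_pred[pos] == 1).mean()) if pos.any() else np.nan
    spec = float((y_pred[neg] == 0).mean()) if neg.any() else np.nan
    acc = float((y_pred == y_true).mean())
    return acc, sens, spec


def crossvalidate_signature(
    m: pd.DataFrame,
    ann: pd.DataFrame,
    config: CvConfig | None = None,
    rank_on_full_data: bool = False,
) -> CvResult:
    """Repeated stratified k-fold CV with per-fold filter feature selection.

    ``rank_on_full_data=True`` deliberately ranks features once on the whole
    matrix before splitting — an information leak that inflates accuracy on
    null data. It exists only as a diagnostic contrast to the honest
    procedure and must not be used for reported results.
    """
    config = config or CvConfig()
    config.validate()
    groups = ann.set_index("sample_id").loc[list(m.columns), "group"]
    y = groups.isin(config.positive_groups).to_numpy().astype(int)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    X = m.to_numpy(dtype=float).T  # samples x features
    feature_ids = list(m.index)

    sizes = config.subset_sizes or log_spaced_subset_sizes(len(feature_ids))
    clipped = [min(s, len(feature_ids)) for s in sizes]
    if clipped != list(sizes):
        warnings.warn("subset sizes above the feature count were clipped", stacklevel=2)
    sizes = sorted(dict.fromkeys(clipped))

    leaky_order: list[int] | None = None
    if rank_on_full_data:
        p_full = _welch_pvalues(X[y == 1].T, X[y == 0].T)
        leaky_order = sorted(range(len(p_full)), key=lambda i: (p_full[i], feature_ids[i]))

    rows = []
    counts: dict[int, Counter] = {s: Counter() for s in sizes}
    for rep in range(config.n_repetitions):
        skf = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True,
            random_state=reseed(config.seed, 1, rep),
        )
        preds = {s: np.empty_like(y) for s in sizes}
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            if leaky_order is not None:
                order = leaky_order
            else:
                p_tr = _welch_pvalues(X[tr][y[tr] == 1].T, X[tr][y[tr] == 0].T)
                order = sorted(range(len(p_tr)), key=lambda i: (p_tr[i], feature_ids[i]))
            for s in sizes:
                feats = order[:s]
                kernel, cost = _choose_model(
                    X[np.ix_(tr, feats)], y[tr], config,
                    seed=reseed(config.seed, 2, rep, fold, s),
                )
                clf = _svm(kernel, cost, config)
                clf.fit(X[np.ix_(tr, feats)], y[tr])
                preds[s][te] = clf.predict(X[np.ix_(te, feats)])
                counts[s].update(feature_ids[i] for i in feats)
        for s in sizes:
            acc, sens, spec = _rates(y, preds[s])
            rows.append(
                {"rep": rep, "subset_size": s, "accuracy": acc,
                 "sensitivity": sens, "specificity": spec}
            )

    per_rep = pd.DataFrame(rows)
    grouped = per_rep.groupby("subset_size")
    summary = grouped[["accuracy", "sensitivity", "specificity"]].mean()
    for rate in ("accuracy", "sensitivity", "specificity"):
        summary[f"{rate}_ci_low"] = grouped[rate].quantile(0.025)
        summary[f"{rate}_ci_high"] = grouped[rate].quantile(0.975)

    best_size = int(summary["accuracy"].idxmax())  # idxmax takes the smallest s on ties
    freq = {
        fid: counts[best_size][fid] / (config.n_repetitions * config.n_folds)
        for fid in counts[best_size]
    }
    signature = tuple(
        sorted(freq, key=lambda fid: (-freq[fid], fid))[:best_size]
    )
    return CvResult(
        per_repetition=per_rep,
        summary=summary,
        best_size=best_size,
        signature=signature,
        selection_frequency=freq,
    )


def permutation_test(
    m: pd.DataFrame,
    ann: pd.DataFrame,
    config: CvConfig | None = None,
    n_permutations: int = 100,
) -> PermutationResult:
    """Re-run the full CV procedure on label-permuted cohorts.

    Class labels are shuffled across samples (class counts preserved); each
    permutation reports the mean rates at its best subset size, matching how
    the true-label result is summarized.
    """
    if n_permutations <= 0:
        raise ValueError("n_permutations must be > 0")
    config = config or CvConfig()
    rng = np.random.default_rng(reseed(config.seed, 3))
    rows = []
    for i in range(n_permutations):
        perm_ann = ann.copy()
        perm_ann["group"] = rng.permutation(ann["group"].to_numpy())
        perm_config = CvConfig(
            **{**config.__dict__, "seed": reseed(config.seed, 4, i)}
        )
        result = crossvalidate_signature(m, perm_ann, perm_config)
        rates = result.rates_at_best()
        rows.append(
            {"permutation": i, "accuracy": rates["accuracy"],
             "sensitivity": rates["sensitivity"], "specificity": rates["specificity"]}
        )
    per_perm = pd.DataFrame(rows)
    quantiles = per_perm[["accuracy", "sensitivity", "specificity"]].quantile(
        [0.025, 0.5, 0.95, 0.975]
    )
    return PermutationResult(per_permutation=per_perm, quantiles=quantiles)


@dataclass(frozen=True)
class FittedSignature:
    """A probability-calibrated SVM over a fixed feature signature."""

    model: Pipeline
    features: tuple[str, ...]
    positive_groups: tuple[str, ...]


def fit_signature_model(
    m: pd.DataFrame,
    ann: pd.DataFrame,
    features,
    kernel: str = "radial",
    cost: float = 1.0,
    positive_groups=("M", "N"),
    seed: int = 0,
) -> FittedSignature:
    """Train a probability-calibrated SVM on the given signature features."""
    features = tuple(features)
    missing = [f for f in features if f not in m.index]
    if missing:
        raise KeyError(f"features absent from matrix: {missing[:5]}")
    groups = ann.set_index("sample_id").loc[list(m.columns), "group"]
    y = groups.isin(tuple(positive_groups)).to_numpy().astype(int)
    X = m.loc[list(features)].to_numpy(dtype=float).T
    from sklearn.calibration import CalibratedClassifierCV

    base = SVC(kernel=CvConfig().sklearn_kernel(kernel), C=cost, gamma="scale",
               random_state=seed)
    clf = Pipeline([
        ("scale", StandardScaler()),
        ("svc", CalibratedClassifierCV(base, method="sigmoid", ensemble=False)),
    ])
    clf.fit(X, y)
    return FittedSignature(model=clf, features=features, positive_groups=tuple(positive_groups))


def score_samples(fitted: FittedSignature, m: pd.DataFrame) -> pd.DataFrame:
    """Per-sample log probability quotient log(P(melanoma)/P(healthy)).

    Positive scores predict melanoma; a score of exactly zero is called
    healthy by convention.
    """
    missing = [f for f in fitted.features if f not in m.index]
    if missing:
        raise KeyError(f"features absent from matrix: {missing[:5]}")
    X = m.loc[list(fitted.features)].to_numpy(dtype=float).T
    proba = fitted.model.predict_proba(X)
    pos_col = int(np.flatnonzero(fitted.model.classes_ == 1)[0])
    p_dis = np.clip(proba[:, pos_col], _PROB_EPS, 1 - _PROB_EPS)
    log_quotient = np.log(p_dis / (1.0 - p_dis))
    return pd.DataFrame(
        {
            "sample_id": list(m.columns),
            "log_quotient": log_quotient,
            "predicted": np.where(log_quotient > 0, "melanoma", "healthy"),
        }
    )
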