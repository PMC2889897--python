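"""Synthetic probe-level cohorts and matched qPCR panels.

The generator emulates the data structure the downstream analysis assumes:
each feature (a miRNA probe) is spotted in ``n_replicates`` replicates per
array, fluorescence is log-normal around a feature-specific baseline, an
additive background is drawn per spot, a chosen subset of features carries a
planted case/control effect on the log2 scale, and the validation arm of the
case group receives a small feature-wise batch offset so the two melanoma
arms agree strongly but not perfectly.

Groups follow the study layout: ``C`` healthy controls, ``M`` melanoma test
set, ``N`` melanoma validation set.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig

# Planted markers stay inside the array's dynamic range in both groups:
# below ~2^7 a marker drowns in the detection floor regardless of its effect,
# and above the baseline ceiling the scanner would saturate — and features
# pushed past the top of the common distribution distort the reference
# quantiles for every other high-intensity feature.
_MIN_PLANTABLE_LOG2 = 7.0
_FLOOR_LOG2_RANGE = (2.0, 6.0)

ENDOGENOUS_CONTROL = "RNU48"


@dataclass(frozen=True)
class ProbeLevelData:
    """Raw per-feature, per-sample, per-replicate intensities with background."""

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    intensity: np.ndarray  # (features, samples, replicates), >= 0
    background: np.ndarray  # same shape

    def __post_init__(self) -> None:
        if self.intensity.shape != self.background.shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} != "
                f"background shape {self.background.shape}"
            )
        if self.intensity.shape[:2] != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("intensity shape inconsistent with feature/sample ids")

    @property
    def n_replicates(self) -> int:
        return self.intensity.shape[2]

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format view: feature_id, sample_id, replicate_index, intensity, background."""
        f, s, r = self.intensity.shape
        fi, si, ri = np.meshgrid(
            np.arange(f), np.arange(s), np.arange(r), indexing="ij"
        )
        return pd.DataFrame(
            {
                "feature_id": np.asarray(self.feature_ids)[fi.ravel()],
                "sample_id": np.asarray(self.sample_ids)[si.ravel()],
                "replicate_index": ri.ravel(),
                "intensity": self.intensity.ravel(),
                "background": self.background.ravel(),
            }
        )

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "ProbeLevelData":
        pivot_i = frame.pivot_table(
            index="feature_id", columns=["sample_id", "replicate_index"],
            values="intensity", sort=False,
        )
        pivot_b = frame.pivot_table(
            index="feature_id", columns=["sample_id", "replicate_index"],
            values="background", sort=False,
        )
        if pivot_i.isna().any().any() or pivot_b.isna().any().any():
            raise ValueError("probe-level table has missing cells")
        samples = list(dict.fromkeys(frame["sample_id"]))
        reps = sorted(frame["replicate_index"].unique())
        f = len(pivot_i.index)
        inten = np.empty((f, len(samples), len(reps)))
        bg = np.empty_like(inten)
        for j, s in enumerate(samples):
            inten[:, j, :] = pivot_i[s].to_numpy()[:, np.argsort(np.argsort(reps))]
            bg[:, j, :] = pivot_b[s].to_numpy()[:, np.argsort(np.argsort(reps))]
        return cls(tuple(pivot_i.index), tuple(samples), inten, bg)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of the planted differential features."""

    planted_ids: tuple[str, ...]
    direction: dict[str, str]  # feature_id -> {"up", "down"}
    log2_effect: dict[str, float]  # signed effect (melanoma minus control)
    feature_ids: tuple[str, ...] = field(default=())  # full generated universe

    def effect_of(self, feature_id: str) -> float:
        """Signed log2 effect; 0 for unplanted features of the cohort."""
        if self.feature_ids and feature_id not in self.feature_ids:
            raise KeyError(f"unknown feature id: {feature_id}")
        return self.log2_effect.get(feature_id, 0.0)


@dataclass(frozen=True)
class QpcrPanel:
    """Ct values for a picked miRNA panel plus an endogenous control per sample."""

    samples: pd.DataFrame  # columns sample_id, group
    ct: pd.DataFrame  # rows = sample_id, columns = miRNA ids + control
    control_id: str = ENDOGENOUS_CONTROL

    @property
    def mirna_ids(self) -> list[str]:
        return [c for c in self.ct.columns if c != self.control_id]

    def to_long_frame(self) -> pd.DataFrame:
        long = self.ct.reset_index(names="sample_id").melt(
            id_vars="sample_id", var_name="mirna_id", value_name="ct"
        )
        long = long.merge(self.samples, on="sample_id")
        long["is_control"] = long["mirna_id"] == self.control_id
        return long[["sample_id", "group", "mirna_id", "ct", "is_control"]]


def _feature_names(n: int) -> tuple[str, ...]:
    width = max(4, len(str(n)))
    return tuple(f"syn-miR-{i:0{width}d}" for i in range(1, n + 1))


def _sample_names(config: SimulationConfig) -> tuple[tuple[str, ...], np.ndarray]:
    names, groups = [], []
    for prefix, count in (("C", config.n_control), ("M", config.n_test), ("N", config.n_validation)):
        for i in range(1, count + 1):
            names.append(f"{prefix}{i:02d}")
            groups.append(prefix)
    return tuple(names), np.asarray(groups)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[ProbeLevelData, pd.DataFrame, SyntheticTruth]:
    """Simulate a probe-level cohort with planted differential features.

    Returns the probe-level data, a sample annotation table
    (``sample_id``, ``group``) and the planted truth. Identical config
    (including seed) gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    features = _feature_names(config.n_features)
    sample_ids, groups = _sample_names(config)
    n_samples = len(sample_ids)

    lo, hi = config.baseline_log2_range
    baseline = rng.uniform(lo, hi, size=config.n_features)

    # A fixed fraction of features sits below the detection floor.
    n_floor = int(round(config.detection_floor_frac * config.n_features))
    floor_idx = rng.choice(config.n_features, size=n_floor, replace=False)
    baseline[floor_idx] = rng.uniform(*_FLOOR_LOG2_RANGE, size=n_floor)

    # Plant effects on expressed features with enough headroom that the
    # shifted group mean stays inside [detection floor, baseline ceiling].
    plantable = set(
        np.setdiff1d(np.flatnonzero(baseline >= _MIN_PLANTABLE_LOG2), floor_idx)
    )
    n_down = int(round(config.frac_down * config.n_planted))
    magnitudes = rng.uniform(*config.effect_range, size=config.n_planted)
    signs = np.ones(config.n_planted)
    signs[:n_down] = -1.0
    effects = np.zeros(config.n_features)
    planted_idx = np.empty(config.n_planted, dtype=int)
    for slot, e in enumerate(signs * magnitudes):
        lo_req = _MIN_PLANTABLE_LOG2 + max(0.0, -e)
        hi_req = hi - max(0.0, e)
        eligible = sorted(i for i in plantable if lo_req <= baseline[i] <= hi_req)
        if not eligible:
            raise ValueError(
                f"cannot plant a {e:+.2f} log2 effect: no feature has baseline "
                f"in [{lo_req:.2f}, {hi_req:.2f}]"
            )
        pick = int(rng.choice(eligible))
        plantable.remove(pick)
        planted_idx[slot] = pick
        effects[pick] = e

    is_case = groups != "C"
    is_validation = groups == "N"
    batch = rng.normal(0.0, config.batch_shift_sd, size=config.n_features)

    # log2 mean per (feature, sample)
    log2_mean = (
        baseline[:, None]
        + np.outer(effects, is_case.astype(float))
        + np.outer(batch, is_validation.astype(float))
    )
    noise = rng.normal(
        0.0, config.replicate_sd, size=(config.n_features, n_samples, config.n_replicates)
    )
    signal = np.exp2(log2_mean[:, :, None] + noise)
    background = np.clip(
        rng.normal(
            config.background_mean,
            config.background_sd,
            size=signal.shape,
        ),
        0.0,
        None,
    )
    data = ProbeLevelData(features, sample_ids, signal + background, background)
    annotation = pd.DataFrame({"sample_id": sample_ids, "group": groups})
    order = np.argsort(planted_idx)  # stable id order in the truth record
    truth = SyntheticTruth(
        planted_ids=tuple(features[i] for i in planted_idx[order]),
        direction={
            features[i]: ("up" if effects[i] > 0 else "down") for i in planted_idx
        },
        log2_effect={features[i]: float(effects[i]) for i in planted_idx},
        feature_ids=features,
    )
    return data, annotation, truth


def generate_qpcr_panel(
    truth: SyntheticTruth,
    picked: list[str] | tuple[str, ...],
    n_per_group: int = 10,
    ct_sd: float = 0.2,
    seed: int = 0,
    control_id: str = ENDOGENOUS_CONTROL,
) -> QpcrPanel:
    """Simulate a qPCR validation panel for ``picked`` miRNAs.

    The Ct model is ``Ct = a - log2(relative abundance) + noise`` with a
    shared intercept per miRNA: case-group Ct values shift by minus the
    planted log2 effect (more abundant -> earlier amplification -> lower Ct);
    the endogenous control has no group effect. ``n_per_group`` case and
    control samples are drawn.
    """
    if n_per_group <= 0:
        raise ValueError("n_per_group must be > 0")
    picked = list(picked)
    for fid in picked:
        truth.effect_of(fid)  # raises KeyError on unknown ids
    rng = np.random.default_rng(seed)
    sample_ids = [f"qC{i:02d}" for i in range(1, n_per_group + 1)] + [
        f"qM{i:02d}" for i in range(1, n_per_group + 1)
    ]
    group = ["C"] * n_per_group + ["M"] * n_per_group
    is_case = np.asarray(group) == "M"

    ct = {}
    for fid in picked:
        base_ct = rng.uniform(22.0, 30.0)
        shift = -truth.effect_of(fid) * is_case.astype(float)
        ct[fid] = base_ct + shift + rng.normal(0.0, ct_sd, size=len(sample_ids))
    ct[control_id] = 20.0 + rng.normal(0.0, ct_sd, size=len(sample_ids))
    frame = pd.DataFrame(ct, index=pd.Index(sample_ids, name="sample_id"))
    samples = pd.DataFrame({"sample_id": sample_ids, "group": group})
    return QpcrPanel(samples=samples, ct=frame, control_id=control_id)


def write_probe_tsv(data: ProbeLevelData, path) -> None:
    data.to_long_frame().to_csv(path, sep="\t", index=False)


def read_probe_tsv(path) -> ProbeLevelData:
    return ProbeLevelData.from_long_frame(pd.read_csv(path, sep="\t"))


def write_truth_tsv(truth: SyntheticTruth, path) -> None:
    pd.DataFrame(
        {
            "feature_id": truth.planted_ids,
            "direction": [truth.direction[f] for f in truth.planted_ids],
            "log2_effect": [truth.log2_effect[f] for f in truth.planted_ids],
        }
    ).to_csv(path, sep="\t", index=False)
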