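"""Configuration objects for the simulation, filtering and classification stages.

All stages draw their randomness from an explicit integer seed carried by the
relevant config, so a pipeline run is reproducible from its config alone.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

DOWN_FRACTION_DEFAULT = 21 / 51  # observed down/total split among the planted markers


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic probe-level cohort.

    The defaults describe a cohort shaped like the study the pipeline targets:
    866 miRNA features spotted in 7 replicates on each of 55 arrays
    (20 healthy controls ``C``, 24 melanoma test samples ``M``, 11 melanoma
    validation samples ``N``), with 51 planted differential features of
    1–3 log2-fold effect in both directions.

    Intensities are simulated on the log2 scale and exponentiated; an additive
    fluorescence background is drawn per spot and recorded so downstream
    background subtraction is well-defined.
    """

    n_features: int = 866
    n_control: int = 20
    n_test: int = 24
    n_validation: int = 11
    n_replicates: int = 7
    n_planted: int = 51
    effect_range: tuple[float, float] = (1.0, 3.0)
    frac_down: float = DOWN_FRACTION_DEFAULT
    baseline_log2_range: tuple[float, float] = (5.0, 14.0)
    replicate_sd: float = 0.25
    background_mean: float = 50.0
    background_sd: float = 15.0
    detection_floor_frac: float = 0.15
    batch_shift_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_features": self.n_features,
            "n_control": self.n_control,
            "n_test": self.n_test,
            "n_validation": self.n_validation,
            "n_replicates": self.n_replicates,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if self.n_planted < 0 or self.n_planted > self.n_features:
            raise ValueError(
                f"n_planted must be in [0, n_features]; got {self.n_planted} "
                f"with n_features={self.n_features}"
            )
        if not 0.0 <= self.frac_down <= 1.0:
            raise ValueError(f"frac_down must be in [0, 1], got {self.frac_down}")
        if self.effect_range[0] > self.effect_range[1]:
            raise ValueError("effect_range must be (low, high) with low <= high")
        if not 0.0 <= self.detection_floor_frac <= 1.0:
            raise ValueError("detection_floor_frac must be in [0, 1]")
        for name in ("replicate_sd", "background_sd", "batch_shift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class FilterCriteria:
    """Stringency filters applied to the per-miRNA marker table.

    A marker is kept when every test's BH-adjusted p-value falls below
    ``alpha``, its fold quotient is at least ``min_fold``-fold in either
    direction, and at least one group median reaches ``min_median`` intensity
    units (features whose medians are low in *both* groups are treated as
    background noise).
    """

    alpha: float = 0.001
    min_fold: float = 2.0
    min_median: float = 100.0

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_fold < 1.0:
            raise ValueError(f"min_fold must be >= 1, got {self.min_fold}")
        if self.min_median < 0.0:
            raise ValueError(f"min_median must be >= 0, got {self.min_median}")


def log_spaced_subset_sizes(n_features: int) -> tuple[int, ...]:
    """Doubling grid 1, 2, 4, ... capped and terminated at ``n_features``."""
    sizes: list[int] = []
    s = 1
    while s < n_features:
        sizes.append(s)
        s *= 2
    sizes.append(n_features)
    return tuple(sizes)


@dataclass(frozen=True)
class CvConfig:
    """Repeated stratified 10-fold cross-validation of the SVM signature.

    ``subset_sizes`` is the grid of filter subset sizes *s* (top-*s* features
    by training-split t-test); ``None`` means a log-spaced grid over the
    feature count, computed when the matrix is seen. Model choice over
    ``kernels`` x ``cost_grid`` happens by nested CV on each training split.
    """

    n_folds: int = 10
    n_repetitions: int = 100
    subset_sizes: tuple[int, ...] | None = None
    cost_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    kernels: tuple[str, ...] = ("radial",)
    positive_groups: tuple[str, ...] = ("M", "N")
    inner_folds: int = 3
    seed: int = 0

    _KERNEL_MAP = {
        "linear": "linear",
        "polynomial": "poly",
        "sigmoid": "sigmoid",
        "radial": "rbf",
    }

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if any(c <= 0 for c in self.cost_grid):
            raise ValueError("all costs must be > 0")
        unknown = set(self.kernels) - set(self._KERNEL_MAP)
        if unknown:
            raise ValueError(f"unknown kernels: {sorted(unknown)}")
        if self.subset_sizes is not None and any(s < 1 for s in self.subset_sizes):
            raise ValueError("subset sizes must be >= 1")

    def sklearn_kernel(self, kernel: str) -> str:
        return self._KERNEL_MAP[kernel]


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (simulate -> ... -> concordance)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filters: FilterCriteria = field(default_factory=FilterCriteria)
    cv: CvConfig = field(default_factory=CvConfig)
    top_variance_k: int = 50
    n_permutations: int = 10
    qpcr_panel_size: int = 13
    qpcr_n_per_group: int = 10
    qpcr_ct_sd: float = 0.2
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        self.simulation.validate()
        self.filters.validate()
        self.cv.validate()
        if self.top_variance_k <= 0:
            raise ValueError("top_variance_k must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, sub in (
            ("simulation", SimulationConfig),
            ("filters", FilterCriteria),
            ("cv", CvConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                section = dict(kwargs[key])
                for tup_key in ("effect_range", "baseline_log2_range", "subset_sizes",
                                "cost_grid", "kernels", "positive_groups"):
                    if tup_key in section and isinstance(section[tup_key], list):
                        section[tup_key] = tuple(section[tup_key])
                kwargs[key] = sub(**section)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def reseed(seed: int, *salt: int) -> int:
    """Derive a child seed below 2**31 from a parent seed and salt integers."""
    import numpy as np

    ss = np.random.SeedSequence([int(seed), *map(int, salt)])
    return int(ss.generate_state(1, dtype="uint32")[0] % (2**31))
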