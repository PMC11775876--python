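"""Run configuration: every tunable constant of the pipeline in one place."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Hyperparameter search space of the posture classifier. Keys are XGBoost
#: parameter names, values (low, high) bounds; max_depth is integer-valued.
POSTURE_SEARCH_SPACE: dict[str, tuple[float, float]] = {
    "max_depth": (2, 6),
    "gamma": (0.5, 10),
    "eta": (0.05, 0.3),
    "reg_alpha": (1, 50),
    "reg_lambda": (1, 10),
    "subsample": (0.8, 1),
    "colsample_bytree": (0.5, 1),
    "min_child_weight": (0, 10),
}

INTEGER_PARAMS = ("max_depth",)


@dataclass
class RunConfig:
    """Pipeline constants.

    Defaults reproduce the published processing chain: 6-s epochs with 50%
    overlap aggregated ten-to-one into 30-s windows, a 6-window (3-min) VM
    lag, a top-30% within-subject stress threshold, an SVM cost grid over
    [2, 16] and a Bonferroni-split model-comparison alpha of 0.05/2.
    """

    epoch_len_s: float = 6.0
    epoch_overlap: float = 0.5
    window_len_s: float = 30.0
    lag_windows: int = 6
    stress_threshold_fraction: float = 0.30
    svm_cost_range: tuple[float, float] = (2.0, 16.0)
    boosted_tree_search_space: dict = field(
        default_factory=lambda: dict(POSTURE_SEARCH_SPACE)
    )
    conv_lr: float = 0.01
    conv_decay: float = 1e-4
    conv_nesterov_momentum: float = 0.9
    conv_iterations: int = 100
    alpha_model_comparison: float = 0.025
    vm_mode: str = "norm"  # "norm" = per-sample Euclidean norm, "rms" = norm/sqrt(3)
    hr_mode: str = "ibi_mean"  # or "rate_mean": mean of 60000/IBI
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epoch_len_s, self.window_len_s) <= 0:
            raise ValueError("lengths must be strictly positive")
        if not 0 < self.epoch_overlap < 1:
            raise ValueError("epoch_overlap must be in (0, 1)")
        if not 0 < self.stress_threshold_fraction < 1:
            raise ValueError("stress_threshold_fraction must be in (0, 1)")
        if self.lag_windows <= 0:
            raise ValueError("lag_windows must be strictly positive")
        if self.vm_mode not in ("norm", "rms"):
            raise ValueError("vm_mode must be 'norm' or 'rms'")
        if self.hr_mode not in ("ibi_mean", "rate_mean"):
            raise ValueError("hr_mode must be 'ibi_mean' or 'rate_mean'")

    @property
    def epoch_step_s(self) -> float:
        return self.epoch_len_s * (1 - self.epoch_overlap)

    @property
    def epochs_per_window(self) -> int:
        return int(round(self.window_len_s / self.epoch_step_s))

    @property
    def tpe_budget(self) -> int:
        """Bayesian-search budget: 10 evaluations per ordinal hyperparameter."""
        return 10 * len(self.boosted_tree_search_space)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["svm_cost_range"] = list(self.svm_cost_range)
        d["boosted_tree_search_space"] = {
            k: list(v) for k, v in self.boosted_tree_search_space.items()
        }
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "svm_cost_range" in d:
            d["svm_cost_range"] = tuple(d["svm_cost_range"])
        if "boosted_tree_search_space" in d:
            d["boosted_tree_search_space"] = {
                k: tuple(v) for k, v in d["boosted_tree_search_space"].items()
            }
        return cls(**d)

    def config_hash(self) -> str:
        """Stable digest of the configuration, recorded in run manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
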