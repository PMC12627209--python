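"""Run configuration: explicit defaults, JSON round-tripping.

Every tunable of the pipeline appears here with its default, so a
serialized config written next to a run's outputs fully documents what
was done.  Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional, Sequence


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    # color wheel
    n_hues: int = 48
    jnd_per_step: float = 1.0
    # session
    n_trials: int = 450
    n_observers: int = 1
    offset_probabilities: Optional[Sequence[float]] = None  # None = uniform over 15
    # observer model used by `simulate`
    model: str = "subsampling"  # subsampling | veridical | none
    model_N: int = 30
    model_sigma: float = 5.0
    model_response_noise_sd: float = 0.0
    # analysis
    davies_k: int = 10
    regression_level: str = "trial"  # trial | offset
    # fitting
    sigma_lo: float = 0.05
    sigma_hi: float = 20.0
    sigma_xatol: float = 1e-3
    log_floor: float = 1e-12
    # parameter recovery
    recovery_n_runs: int = 400
    recovery_trials_per_run: int = 450
    recovery_n_lo: int = 1
    recovery_n_hi: int = 36
    recovery_sigma_lo: float = 0.5
    recovery_sigma_hi: float = 10.0
    # global
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.model not in ("subsampling", "veridical", "none"):
            raise ConfigError(
                f"model must be 'subsampling', 'veridical' or 'none', got {self.model!r}"
            )
        if self.regression_level not in ("trial", "offset"):
            raise ConfigError(
                f"regression_level must be 'trial' or 'offset', got {self.regression_level!r}"
            )
        if self.n_trials < 1:
            raise ConfigError(f"n_trials must be >= 1, got {self.n_trials}")
        if self.n_observers < 1:
            raise ConfigError(f"n_observers must be >= 1, got {self.n_observers}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as err:
            raise ConfigError(str(err)) from err

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
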