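"""Run configuration: validated defaults, TOML loading, stable hashing."""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

from .errors import InvalidConfigError
from .model import HyperparamGrid
from .segmentation import LabThresholdSpec

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Everything a reproducible extract+fit run depends on.

    Thresholds are on the 0-255 Lab scale; fleck class bounds in mm²;
    ``seed`` is the single master seed feeding the split, CV ordering and
    model fitting.
    """

    lab_l: tuple[float, float] = (0.0, 255.0)
    lab_a: tuple[float, float] = (0.0, 255.0)
    lab_b: tuple[float, float] = (0.0, 129.0)
    small_min: float = 1.0
    small_max: float = 50.0
    connectivity: int = 8
    binarization: str = "isodata"
    px_per_mm: float = 4.0
    resize_target: int = 500
    test_fraction: float = 0.2
    n_folds: int = 10
    cv_window: int = 1
    max_depth: tuple[int, ...] = (2, 3, 4)
    learning_rate: tuple[float, ...] = (0.05, 0.1, 0.3)
    n_estimators_max: int = 500
    early_stopping_rounds: int = 15
    seed: int = 0
    input_dir: str = "."
    output_dir: str = "."

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        LabThresholdSpec(tuple(self.lab_l), tuple(self.lab_a), tuple(self.lab_b))
        if not (0 < self.small_min < self.small_max):
            raise InvalidConfigError("need 0 < small_min < small_max")
        if self.connectivity not in (4, 8):
            raise InvalidConfigError("connectivity must be 4 or 8")
        if self.binarization not in ("isodata", "otsu"):
            raise InvalidConfigError("binarization must be 'isodata' or 'otsu'")
        if not self.px_per_mm > 0:
            raise InvalidConfigError("px_per_mm must be positive")
        if self.resize_target < 8:
            raise InvalidConfigError("resize_target must be >= 8")
        if not 0 < self.test_fraction < 1:
            raise InvalidConfigError("test_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise InvalidConfigError("n_folds must be >= 2")
        if self.cv_window < 1:
            raise InvalidConfigError("cv_window must be >= 1")

    @property
    def threshold_spec(self) -> LabThresholdSpec:
        return LabThresholdSpec(tuple(self.lab_l), tuple(self.lab_a), tuple(self.lab_b))

    @property
    def grid(self) -> HyperparamGrid:
        return HyperparamGrid(
            max_depth=tuple(self.max_depth),
            learning_rate=tuple(self.learning_rate),
            n_estimators_max=self.n_estimators_max,
            early_stopping_rounds=self.early_stopping_rounds,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Stable short hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a TOML config file; unknown keys are rejected, keyword
    overrides win over file values."""
    data = tomllib.loads(Path(path).read_text())
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
    data.update(overrides)
    for key in ("lab_l", "lab_a", "lab_b", "max_depth", "learning_rate"):
        if key in data:
            data[key] = tuple(data[key])
    try:
        return RunConfig(**data)
    except TypeError as exc:  # e.g. wrong value type for a field
        raise InvalidConfigError(str(exc)) from exc
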