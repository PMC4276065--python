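"""Pipeline configuration.

Every numeric constant of the processing protocol lives here so that a run is
fully described by one config object: the 100 mg MVPA threshold on 5-s epochs,
the 60-min/15-min non-wear windowing with 13 mg SD and 50 mg range criteria on
at least two axes, the 10 h head / 20 h tail exclusion, the 0.02 g
post-calibration error gate, the every-15-min-slot validity rule, the 5- and
10-min bout lengths with the 80% criterion, and the 40-mg intensity bins.

Internal unit for acceleration is g throughout; thresholds named ``*_mg`` are
converted at the single point of use.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised for unknown keys or invariant-violating configuration values."""


@dataclass(frozen=True)
class PipelineConfig:
    # ENMO / epochs
    enmo_truncate_negative: bool = True
    epoch_length_s: int = 5
    # non-wear detection
    nonwear_window_min: int = 60
    nonwear_step_min: int = 15
    nonwear_sd_threshold_mg: float = 13.0
    nonwear_range_threshold_mg: float = 50.0
    nonwear_axes_required: int = 2
    # boundary exclusion
    head_exclusion_h: float = 10.0
    tail_exclusion_h: float = 20.0
    # calibration
    calibration_error_max_g: float = 0.02
    stationary_window_s: float = 10.0
    stationary_sd_threshold_mg: float = 13.0
    sphere_coverage_g: float = 0.3
    # clipping
    clip_fraction: float = 0.95
    clip_min_duration_s: float = 10.0
    # validity
    validity_slot_min: int = 15
    min_valid_days: int = 2
    valid_day_min_wear_h: float = 16.0
    # activity summaries
    mvpa_threshold_mg: float = 100.0
    bout_lengths_min: tuple[int, ...] = (5, 10)
    bout_fraction: float = 0.80
    bout_mode: str = "union"  # or "greedy"
    intensity_bin_width_mg: float = 40.0

    def __post_init__(self) -> None:
        positive = [
            "epoch_length_s", "nonwear_window_min", "nonwear_step_min",
            "nonwear_sd_threshold_mg", "nonwear_range_threshold_mg",
            "nonwear_axes_required", "head_exclusion_h", "tail_exclusion_h",
            "calibration_error_max_g", "stationary_window_s",
            "stationary_sd_threshold_mg", "sphere_coverage_g",
            "clip_fraction", "clip_min_duration_s", "validity_slot_min",
            "min_valid_days", "valid_day_min_wear_h", "mvpa_threshold_mg",
            "intensity_bin_width_mg",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be strictly positive")
        if not (0 < self.bout_fraction <= 1):
            raise ConfigError("bout_fraction must lie in (0, 1]")
        if self.nonwear_window_min % self.nonwear_step_min != 0:
            raise ConfigError(
                "nonwear_step_min must divide nonwear_window_min "
                f"({self.nonwear_step_min} does not divide {self.nonwear_window_min})"
            )
        if 86400 % self.epoch_length_s != 0:
            raise ConfigError("epoch_length_s must divide 86400")
        if self.bout_mode not in ("union", "greedy"):
            raise ConfigError("bout_mode must be 'union' or 'greedy'")
        if any(L <= 0 for L in self.bout_lengths_min):
            raise ConfigError("bout lengths must be positive")
        for L in self.bout_lengths_min:
            if (L * 60) % self.epoch_length_s != 0:
                raise ConfigError(
                    f"bout length {L} min is not a whole number of epochs"
                )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bout_lengths_min"] = list(d["bout_lengths_min"])
        return d

    def digest(self) -> str:
        """Stable hash of the effective configuration, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_FIELDS = {f.name for f in dataclasses.fields(PipelineConfig)}


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML configuration file; unspecified fields take the protocol
    defaults. Unknown keys are rejected (typo protection). ``None`` or an
    empty file yields the all-defaults configuration."""
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        data = loaded
    unknown = set(data) - _FIELDS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "bout_lengths_min" in data:
        data["bout_lengths_min"] = tuple(data["bout_lengths_min"])
    return PipelineConfig(**data)
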