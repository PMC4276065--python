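"""In-memory containers for raw recordings and participant metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEXES = ("male", "female")
SES_QUINTILES = ("Q1", "Q2", "Q3", "Q4", "Q5")
WEIGHT_STATUSES = ("underweight", "normal", "overweight", "obese")


@dataclass
class RawRecording:
    """A raw triaxial acceleration recording in units of g.

    Samples are nominally uniform at ``sample_rate_hz``; sample ``i`` is taken
    at ``start_time + i / sample_rate_hz``. When a file was read back with
    timing irregularities, the true per-sample offsets are kept in
    ``sample_times_s`` (seconds since the midnight preceding ``start_time``)
    and gaps wider than two sample intervals are listed in ``missing_runs``.
    """

    participant_id: str
    start_time: pd.Timestamp
    sample_rate_hz: float
    samples: np.ndarray  # (n, 3) in g
    dynamic_range_g: float = 8.0
    calibrated: bool = False
    sample_times_s: np.ndarray | None = None
    missing_runs: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.dynamic_range_g <= 0:
            raise ValueError("dynamic_range_g must be positive")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples contain non-finite values")
        amax = float(np.abs(self.samples).max(initial=0.0))
        if amax > self.dynamic_range_g * (1 + 1e-9):
            raise ValueError(
                f"sample magnitude {amax:.3f} g exceeds the ±{self.dynamic_range_g} g range"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        if self.sample_times_s is not None:
            return float(self.sample_times_s[-1] - self.sample_times_s[0]) + 1.0 / self.sample_rate_hz
        return self.n_samples / self.sample_rate_hz

    @property
    def day0(self) -> pd.Timestamp:
        """Midnight of the first calendar day of the recording."""
        return self.start_time.normalize()

    @property
    def start_offset_s(self) -> float:
        """Seconds from day0 midnight to the first sample."""
        return float((self.start_time - self.day0).total_seconds())

    def sample_offsets(self) -> np.ndarray:
        """Per-sample time offsets in seconds since day0 midnight."""
        if self.sample_times_s is not None:
            return self.sample_times_s
        return self.start_offset_s + np.arange(self.n_samples) / self.sample_rate_hz

    @property
    def end_offset_s(self) -> float:
        """Offset just past the last sample (start of first sample + duration)."""
        if self.sample_times_s is not None:
            return float(self.sample_times_s[-1]) + 1.0 / self.sample_rate_hz
        return self.start_offset_s + self.duration_s


@dataclass(frozen=True)
class ParticipantMeta:
    """Stratification labels for one participant.

    Strata arrive as closed-set labels; the package neither derives weight
    status from BMI nor constructs the SES index.
    """

    participant_id: str
    sex: str
    cohort: str
    ses_quintile: str
    weight_status: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.ses_quintile not in SES_QUINTILES:
            raise ValueError(
                f"ses_quintile must be one of {SES_QUINTILES}, got {self.ses_quintile!r}"
            )
        if self.weight_status not in WEIGHT_STATUSES:
            raise ValueError(
                f"weight_status must be one of {WEIGHT_STATUSES}, got {self.weight_status!r}"
            )
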