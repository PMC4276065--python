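"""Sample-level metrics and the 5-s epoch grid.

The activity metric is ENMO, the Euclidean norm of the triaxial acceleration
vector minus 1 g, with negative values truncated to zero:

    ENMO = max(0, sqrt(x^2 + y^2 + z^2) - 1)      [g]

Epochs live on a wall-clock grid (multiples of the epoch length counted from
midnight of the recording's first day), not a recording-start grid, so that
epochs on different days at the same clock time share a slot — the property
the time-of-day imputation rule relies on.

Pipeline status order: epochs start out valid/missing at aggregation, then
clipping is applied, then boundary exclusion, then non-wear, and imputation
comes last. Later stages only overwrite the statuses listed in each function.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .recording import RawRecording

logger = logging.getLogger(__name__)


class EpochStatus(enum.IntEnum):
    VALID = 0
    MISSING = 1
    CLIPPED = 2
    EXCLUDED = 3
    NONWEAR = 4
    IMPUTED = 5


#: statuses whose epochs carry no usable measurement and get imputed
INVALID_STATUSES = (
    EpochStatus.MISSING,
    EpochStatus.CLIPPED,
    EpochStatus.EXCLUDED,
    EpochStatus.NONWEAR,
)


@dataclass
class EpochSeries:
    """ENMO epochs on the wall-clock grid.

    ``start_slot`` indexes the first epoch in units of ``epoch_length_s``
    since midnight of ``day0``; slot ``s`` covers wall-clock seconds
    ``[s * L, (s + 1) * L)``.
    """

    participant_id: str
    day0: pd.Timestamp
    epoch_length_s: int
    start_slot: int
    enmo_mg: np.ndarray
    status: np.ndarray  # int8, EpochStatus values
    enmo_original_mg: np.ndarray | None = None  # pre-imputation values, audit
    status_pre_impute: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.enmo_mg = np.asarray(self.enmo_mg, dtype=float)
        self.status = np.asarray(self.status, dtype=np.int8)
        if self.enmo_mg.shape != self.status.shape:
            raise ValueError("enmo_mg and status must have identical shape")

    @property
    def n_epochs(self) -> int:
        return self.enmo_mg.shape[0]

    @property
    def slots(self) -> np.ndarray:
        return self.start_slot + np.arange(self.n_epochs)

    @property
    def seconds_of_day(self) -> np.ndarray:
        return (self.slots * self.epoch_length_s) % 86400

    @property
    def day_index(self) -> np.ndarray:
        return (self.slots * self.epoch_length_s) // 86400

    @property
    def slots_per_day(self) -> int:
        return 86400 // self.epoch_length_s

    def copy(self) -> "EpochSeries":
        return replace(
            self,
            enmo_mg=self.enmo_mg.copy(),
            status=self.status.copy(),
            enmo_original_mg=None if self.enmo_original_mg is None else self.enmo_original_mg.copy(),
            status_pre_impute=None if self.status_pre_impute is None else self.status_pre_impute.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Epoch table with wall-clock start times and status names."""
        start = self.day0 + pd.to_timedelta(self.slots * self.epoch_length_s, unit="s")
        return pd.DataFrame(
            {
                "epoch_start": start,
                "enmo_mg": self.enmo_mg,
                "status": [EpochStatus(s).name.lower() for s in self.status],
            }
        )

    def status_durations_s(self) -> dict[str, float]:
        """Total duration per status; always sums to the grid span."""
        out = {}
        for st in EpochStatus:
            out[st.name.lower()] = float((self.status == st).sum()) * self.epoch_length_s
        return out


def compute_enmo(rec: RawRecording, truncate_negative: bool = True) -> np.ndarray:
    """Per-sample ENMO in g. ``truncate_negative=False`` keeps the signed
    deviation (diagnostic use only; the protocol metric truncates)."""
    if not rec.calibrated:
        logger.warning(
            "computing ENMO on an uncalibrated recording (%s)", rec.participant_id
        )
    s = rec.samples
    norm = np.sqrt(s[:, 0] ** 2 + s[:, 1] ** 2 + s[:, 2] ** 2)
    enmo = norm - 1.0
    if truncate_negative:
        np.maximum(enmo, 0.0, out=enmo)
    return enmo


def detect_clipping(rec: RawRecording, cfg: PipelineConfig | None = None) -> list[tuple[int, int]]:
    """Maximal sample-index runs [i0, i1) of sustained abnormally high values.

    A sample is high when any axis exceeds ``clip_fraction`` of the dynamic
    range in magnitude; a run is sustained when it lasts at least
    ``clip_min_duration_s``.
    """
    cfg = cfg or PipelineConfig()
    thr = cfg.clip_fraction * rec.dynamic_range_g
    high = (np.abs(rec.samples) > thr).any(axis=1)
    if not high.any():
        return []
    min_len = int(np.ceil(cfg.clip_min_duration_s * rec.sample_rate_hz - 1e-9))
    padded = np.concatenate([[False], high, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    return [(int(a), int(b)) for a, b in zip(starts, ends) if b - a >= min_len]


def _edge_indices(rec: RawRecording, edges_s: np.ndarray) -> np.ndarray:
    """Index of the first sample at or after each time offset (seconds since
    day0 midnight)."""
    if rec.sample_times_s is not None:
        return np.searchsorted(rec.sample_times_s, edges_s - 1e-9)
    rel = (edges_s - rec.start_offset_s) * rec.sample_rate_hz
    idx = np.ceil(rel - 1e-9).astype(np.int64)
    return np.clip(idx, 0, rec.n_samples)


def aggregate_epochs(
    rec: RawRecording,
    enmo_g: np.ndarray,
    cfg: PipelineConfig | None = None,
) -> EpochSeries:
    """Aggregate per-sample ENMO to wall-clock-aligned epochs.

    The first epoch starts at the first whole multiple of the epoch length at
    or after the first sample; the grid runs through the last sample, so a
    trailing partial epoch is kept (and marked missing when sample coverage
    falls below 50%). Epoch value is the mean of its samples, in mg.
    """
    cfg = cfg or PipelineConfig()
    L = cfg.epoch_length_s
    t0 = rec.start_offset_s if rec.sample_times_s is None else float(rec.sample_times_s[0])
    t_end = rec.end_offset_s
    start_slot = int(np.ceil(t0 / L - 1e-9))
    end_slot = int(np.ceil(t_end / L - 1e-9))  # one past the last epoch
    n_epochs = max(end_slot - start_slot, 0)
    if n_epochs == 0:
        return EpochSeries(rec.participant_id, rec.day0, L, start_slot,
                           np.empty(0), np.empty(0, dtype=np.int8))
    edges = (start_slot + np.arange(n_epochs + 1)) * float(L)
    bounds = _edge_indices(rec, edges)
    counts = np.diff(bounds)
    cs = np.concatenate([[0.0], np.cumsum(enmo_g, dtype=np.float64)])
    sums = cs[bounds[1:]] - cs[bounds[:-1]]
    with np.errstate(invalid="ignore"):
        means_mg = np.where(counts > 0, sums / np.maximum(counts, 1) * 1000.0, 0.0)
    full = rec.sample_rate_hz * L
    status = np.where(counts >= 0.5 * full, EpochStatus.VALID, EpochStatus.MISSING).astype(np.int8)
    # epochs overlapping recorded gaps keep whatever coverage says; gaps
    # shrink `counts` automatically when sample_times_s is present
    return EpochSeries(rec.participant_id, rec.day0, L, start_slot, means_mg, status)


def apply_clipping(
    es: EpochSeries, rec: RawRecording, intervals: list[tuple[int, int]]
) -> EpochSeries:
    """Mark epochs overlapping any clipped sample run as ``clipped``."""
    out = es.copy()
    if not intervals:
        return out
    offsets = None
    L = es.epoch_length_s
    for i0, i1 in intervals:
        if rec.sample_times_s is not None:
            if offsets is None:
                offsets = rec.sample_times_s
            t_a, t_b = offsets[i0], offsets[i1 - 1] + 1.0 / rec.sample_rate_hz
        else:
            t_a = rec.start_offset_s + i0 / rec.sample_rate_hz
            t_b = rec.start_offset_s + i1 / rec.sample_rate_hz
        s_a = int(np.floor(t_a / L)) - es.start_slot
        s_b = int(np.ceil(t_b / L - 1e-9)) - es.start_slot
        s_a, s_b = max(s_a, 0), min(s_b, es.n_epochs)
        sel = slice(s_a, s_b)
        view = out.status[sel]
        view[view == EpochStatus.VALID] = EpochStatus.CLIPPED
    return out


def exclude_boundaries(
    es: EpochSeries,
    head_h: float | None = None,
    tail_h: float | None = None,
    cfg: PipelineConfig | None = None,
    span_s: tuple[float, float] | None = None,
) -> tuple[EpochSeries, bool]:
    """Mark epochs in the first ``head_h`` and last ``tail_h`` hours as
    ``excluded``; returns (series, all_excluded).

    The exclusion is measured from the first/last sample of the file
    (``span_s``, seconds since day0 midnight; defaults to the epoch-grid
    span), reflecting handling logistics rather than detected wear. A
    recording shorter than head + tail is excluded entirely and reported
    invalid by the caller.
    """
    cfg = cfg or PipelineConfig()
    head_h = cfg.head_exclusion_h if head_h is None else head_h
    tail_h = cfg.tail_exclusion_h if tail_h is None else tail_h
    out = es.copy()
    if es.n_epochs == 0:
        return out, True
    L = es.epoch_length_s
    if span_s is None:
        t0 = es.start_slot * L
        t1 = (es.start_slot + es.n_epochs) * L
    else:
        t0, t1 = span_s
    head_end = t0 + head_h * 3600.0
    tail_start = t1 - tail_h * 3600.0
    starts = es.slots * float(L)
    ends = starts + L
    excl = (starts < head_end - 1e-9) | (ends > tail_start + 1e-9)
    keep_missing = out.status == EpochStatus.MISSING
    out.status[excl & ~keep_missing] = EpochStatus.EXCLUDED
    all_excluded = bool(excl.all()) or tail_start <= head_end
    return out, all_excluded
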