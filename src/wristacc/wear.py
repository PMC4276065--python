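"""Non-wear detection, file/day validity, and time-of-day imputation.

Non-wear is inferred from per-axis variability of the raw signal: 60-min
windows advanced in 15-min increments are classified as non-wear when, on at
least two of the three axes, the sample SD is below 13 mg and the value range
is below 50 mg. Every window on the 15-min grid is evaluated and a 15-min
block is flagged non-wear when at least one qualifying window covers it; the
long window deliberately keeps short still periods — and sleep, which carries
micro-movements — out, so the detector targets episodes longer than an hour.
Windows truncated by the file edges are still evaluated when at least 30 min
of signal remains; blocks covered by no evaluable window are ``unknown`` and
treated as worn (but never imputed from).

File validity combines two gates: post-calibration error below 0.02 g, and
valid data present for every 15-min period of the 24-h clock cycle, even when
scattered over multiple days. Valid days (a participant-inclusion criterion,
not a file gate) are calendar days with at least 16 h of valid wear.

Imputation replaces every invalid epoch by the mean of valid epochs at the
same clock slot on other days; when the exact slot has no valid epoch on any
other day, the mean of valid epochs within the enclosing 15-min clock slot is
used (non-empty whenever the 24-h-cycle rule holds). Original values and
statuses are retained for audit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationResult
from .config import PipelineConfig
from .metrics import INVALID_STATUSES, EpochSeries, EpochStatus, _edge_indices
from .recording import RawRecording


class BlockFlag(enum.IntEnum):
    WORN = 0
    NONWEAR = 1
    UNKNOWN = 2


@dataclass
class NonwearMask:
    """Wear/non-wear flags on the 15-min wall-clock block grid."""

    day0: pd.Timestamp
    block_length_min: int
    start_block: int  # index in units of block_length since day0 midnight
    flags: np.ndarray  # int8, BlockFlag values

    @property
    def n_blocks(self) -> int:
        return self.flags.shape[0]

    @property
    def blocks(self) -> np.ndarray:
        return self.start_block + np.arange(self.n_blocks)

    def nonwear_fraction(self) -> float:
        known = self.flags != BlockFlag.UNKNOWN
        if not known.any():
            return float("nan")
        return float((self.flags == BlockFlag.NONWEAR).sum() / known.sum())

    def to_frame(self) -> pd.DataFrame:
        start = self.day0 + pd.to_timedelta(
            self.blocks * self.block_length_min * 60, unit="s"
        )
        return pd.DataFrame(
            {
                "block_start": start,
                "flag": [BlockFlag(f).name.lower() for f in self.flags],
            }
        )


@dataclass
class ValidityReport:
    file_valid: bool
    reasons: list[str]
    slots_covered: int
    valid_days: int
    per_day_valid_h: list[float]
    calibration_ok: bool
    nonwear_fraction: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "file_valid": self.file_valid,
            "reasons": self.reasons,
            "slots_covered": self.slots_covered,
            "valid_days": self.valid_days,
            "per_day_valid_h": self.per_day_valid_h,
            "calibration_ok": self.calibration_ok,
            "nonwear_fraction": self.nonwear_fraction,
        }


def _combine_moments(n, mean, m2, mn, mx):
    """Pool per-sub-block (count, mean, sum of squared deviations, min, max)
    into window statistics; exact pooling, no cancellation."""
    N = n.sum(axis=0)
    if N.min() == 0:
        return N, None, None
    gm = (n * mean).sum(axis=0) / N
    M2 = (m2 + n * (mean - gm) ** 2).sum(axis=0)
    rng = mx.max(axis=0) - mn.min(axis=0)
    return N, np.sqrt(M2 / N), rng


def detect_nonwear(rec: RawRecording, cfg: PipelineConfig | None = None) -> NonwearMask:
    """Classify 15-min blocks as worn / non-wear / unknown.

    Implementation detail: per-axis sums, squared deviations, minima and
    maxima are first computed on half-step (7.5-min) sub-blocks, then pooled
    into each 60-min window — numerically exact and linear-time in the number
    of samples.
    """
    cfg = cfg or PipelineConfig()
    step_s = cfg.nonwear_step_min * 60
    win_s = cfg.nonwear_window_min * 60
    half_s = step_s / 2.0  # sub-block resolution: window edges sit on half-steps
    t0 = float(rec.sample_times_s[0]) if rec.sample_times_s is not None else rec.start_offset_s
    t_end = rec.end_offset_s

    first_block = int(np.floor(t0 / step_s))
    last_block = int(np.ceil(t_end / step_s))  # one past
    n_blocks = last_block - first_block

    # sub-block edges on the half-step grid covering the recording
    first_half = int(np.floor(t0 / half_s))
    last_half = int(np.ceil(t_end / half_s))
    edges = np.arange(first_half, last_half + 1) * half_s
    edges = np.clip(edges, t0, t_end)
    bounds = _edge_indices(rec, edges)
    n_sub = len(edges) - 1

    s = rec.samples
    cnt = np.diff(bounds).astype(float)
    sub_mean = np.zeros((n_sub, 3))
    sub_m2 = np.zeros((n_sub, 3))
    sub_min = np.full((n_sub, 3), np.inf)
    sub_max = np.full((n_sub, 3), -np.inf)
    for j in range(n_sub):
        a, b = bounds[j], bounds[j + 1]
        if b > a:
            blk = s[a:b]
            m = blk.mean(axis=0, dtype=np.float64)
            sub_mean[j] = m
            d = blk - m
            sub_m2[j] = (d * d).sum(axis=0, dtype=np.float64)
            sub_min[j] = blk.min(axis=0)
            sub_max[j] = blk.max(axis=0)

    sd_thr = cfg.nonwear_sd_threshold_mg / 1000.0
    rng_thr = cfg.nonwear_range_threshold_mg / 1000.0
    win_blocks = win_s // step_s

    flags = np.full(n_blocks, BlockFlag.UNKNOWN, dtype=np.int8)
    covered = np.zeros(n_blocks, dtype=bool)
    evaluable = np.zeros(n_blocks, dtype=bool)

    # windows start at every wall-clock 15-min grid point; edge windows
    # truncated to the recording span are evaluated when >= half remains
    for k in range(first_block - win_blocks + 1, last_block + win_blocks):
        w_lo, w_hi = 2 * k, 2 * k + 2 * win_blocks  # in half-step units
        lo = max(w_lo, first_half)
        hi = min(w_hi, last_half)
        if hi <= lo:
            continue
        dur = float(edges[hi - first_half] - edges[lo - first_half])
        if dur < win_s / 2.0 - 1e-9:
            continue
        sel = slice(lo - first_half, hi - first_half)
        N, sd, vrange = _combine_moments(
            cnt[sel, None] * np.ones(3), sub_mean[sel], sub_m2[sel],
            sub_min[sel], sub_max[sel],
        )
        # blocks of the 15-min grid covered by this window
        b_lo, b_hi = max(k, first_block), min(k + win_blocks, last_block)
        if b_hi <= b_lo:
            continue
        bsel = slice(b_lo - first_block, b_hi - first_block)
        evaluable[bsel] = True
        if sd is None:
            continue
        ax_ok = (sd < sd_thr) & (vrange < rng_thr)
        if int(ax_ok.sum()) >= cfg.nonwear_axes_required:
            covered[bsel] = True

    flags[evaluable] = BlockFlag.WORN
    flags[covered] = BlockFlag.NONWEAR
    return NonwearMask(rec.day0, cfg.nonwear_step_min, first_block, flags)


def merge_nonwear(es: EpochSeries, mask: NonwearMask) -> EpochSeries:
    """Set status ``nonwear`` on currently-valid epochs inside non-wear blocks."""
    out = es.copy()
    if mask.n_blocks == 0:
        return out
    block_s = mask.block_length_min * 60
    epoch_block = (out.slots * out.epoch_length_s) // block_s
    nw_blocks = mask.blocks[mask.flags == BlockFlag.NONWEAR]
    hit = np.isin(epoch_block, nw_blocks)
    sel = hit & (out.status == EpochStatus.VALID)
    out.status[sel] = EpochStatus.NONWEAR
    return out


def assess_validity(
    es: EpochSeries,
    cal: CalibrationResult | None,
    cfg: PipelineConfig | None = None,
    mask: NonwearMask | None = None,
) -> ValidityReport:
    """File validity and valid-day count from merged epoch statuses."""
    cfg = cfg or PipelineConfig()
    reasons: list[str] = []

    cal_ok = True
    if cal is not None:
        err = cal.error_post_g
        cal_ok = bool(np.isfinite(err) and err < cfg.calibration_error_max_g)
        if not cal_ok:
            reasons.append(
                f"post-calibration error {err:.4f} g not below "
                f"{cfg.calibration_error_max_g} g"
            )

    slot_s = cfg.validity_slot_min * 60
    n_slots = 86400 // slot_s
    valid = es.status == EpochStatus.VALID
    slots = np.unique((es.seconds_of_day[valid] // slot_s))
    slots_covered = int(slots.size)
    if slots_covered < n_slots:
        reasons.append(
            f"only {slots_covered}/{n_slots} {cfg.validity_slot_min}-min clock "
            "slots hold valid data"
        )

    per_day_valid_h: list[float] = []
    valid_days = 0
    if es.n_epochs:
        days = es.day_index
        for d in range(int(days.min()), int(days.max()) + 1):
            h = float(valid[days == d].sum()) * es.epoch_length_s / 3600.0
            per_day_valid_h.append(h)
            if h >= cfg.valid_day_min_wear_h:
                valid_days += 1
    if valid_days < cfg.min_valid_days:
        reasons.append(
            f"{valid_days} valid days (>= {cfg.valid_day_min_wear_h:g} h valid "
            f"wear), protocol requires {cfg.min_valid_days}"
        )

    file_valid = cal_ok and slots_covered == n_slots
    nw_frac = mask.nonwear_fraction() if mask is not None else float("nan")
    return ValidityReport(
        file_valid=file_valid,
        reasons=reasons,
        slots_covered=slots_covered,
        valid_days=valid_days,
        per_day_valid_h=per_day_valid_h,
        calibration_ok=cal_ok,
        nonwear_fraction=nw_frac,
    )


def impute(
    es: EpochSeries,
    cfg: PipelineConfig | None = None,
    *,
    require_valid: bool = True,
) -> EpochSeries:
    """Impute invalid epochs from same-clock-slot averages on other days.

    Raises if the series fails the every-15-min-slot coverage rule (the
    fallback average would be undefined). Idempotent: a second call finds no
    invalid epochs and changes nothing; valid epochs are never altered.
    """
    cfg = cfg or PipelineConfig()
    out = es.copy()
    n = out.n_epochs
    if n == 0:
        return out

    slot_len = out.epoch_length_s
    sod = (out.slots * slot_len) % 86400
    exact_slot = sod // slot_len  # 0 .. slots_per_day-1
    block_s = cfg.validity_slot_min * 60
    block_slot = sod // block_s

    valid = out.status == EpochStatus.VALID
    n_exact = out.slots_per_day
    n_block = 86400 // block_s

    if require_valid:
        covered = np.unique(block_slot[valid]).size
        if covered < n_block:
            raise ValueError(
                "refusing to impute an invalid file: only "
                f"{covered}/{n_block} clock slots hold valid data"
            )

    cnt_exact = np.bincount(exact_slot[valid], minlength=n_exact)
    sum_exact = np.bincount(exact_slot[valid], weights=out.enmo_mg[valid], minlength=n_exact)
    cnt_block = np.bincount(block_slot[valid], minlength=n_block)
    sum_block = np.bincount(block_slot[valid], weights=out.enmo_mg[valid], minlength=n_block)

    invalid = np.isin(out.status, np.asarray(INVALID_STATUSES, dtype=np.int8))
    if not invalid.any():
        if out.enmo_original_mg is None:
            out.enmo_original_mg = es.enmo_mg.copy()
            out.status_pre_impute = es.status.copy()
        return out

    out.enmo_original_mg = es.enmo_mg.copy()
    out.status_pre_impute = es.status.copy()

    es_slot = exact_slot[invalid]
    bs_slot = block_slot[invalid]
    have_exact = cnt_exact[es_slot] > 0
    vals = np.where(
        have_exact,
        sum_exact[es_slot] / np.maximum(cnt_exact[es_slot], 1),
        sum_block[bs_slot] / np.maximum(cnt_block[bs_slot], 1),
    )
    if (cnt_block[bs_slot][~have_exact] == 0).any():
        raise ValueError("imputation fallback slot empty; file is not valid")
    out.enmo_mg[invalid] = vals
    out.status[invalid] = EpochStatus.IMPUTED
    return out
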