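"""MVPA bout detection, intensity distributions, and per-person summaries.

A bout of moderate-to-vigorous physical activity (MVPA) is a 5- or 10-min
window that starts with a 5-s epoch at or above the 100 mg threshold and in
which at least 80% of the subsequent epochs are at or above the threshold.
With L epochs per window, window i qualifies iff

    enmo[i] >= threshold  and
    #{ j in (i, i+L) : enmo[j] >= threshold } >= ceil(fraction * (L - 1)).

Time in MVPA counts each above-threshold epoch that lies inside at least one
qualifying window, once (so overlapping bouts never double-count, and the
below-threshold tolerance epochs inside a bout do not inflate the total). A
greedy non-overlapping mode is available behind ``bout_mode = "greedy"``.

Intensity distributions are per-day histograms of epoch ENMO in 40-mg bins
(top bin open-ended); on imputed full days the bin minutes sum to 1440.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .metrics import EpochSeries, EpochStatus


def required_above(bout_length_min: float, fraction: float, epoch_length_s: int) -> tuple[int, int]:
    """(epochs per window L, required above-threshold count among the L-1
    subsequent epochs). Ceiling with a small guard so that exact products
    (0.8 * 60 = 48) are not pushed up by floating-point representation."""
    L = int(round(bout_length_min * 60 / epoch_length_s))
    need = math.ceil(fraction * (L - 1) - 1e-9)
    return L, need


def detect_bouts(
    enmo_mg: np.ndarray,
    bout_length_min: float,
    threshold_mg: float = 100.0,
    fraction: float = 0.80,
    epoch_length_s: int = 5,
    mode: str = "union",
) -> np.ndarray:
    """Boolean in-bout flag per epoch.

    ``union`` marks every above-threshold epoch covered by any qualifying
    window; ``greedy`` accepts qualifying windows left to right without
    overlap. Series shorter than one window yield no bouts.
    """
    x = np.asarray(enmo_mg, dtype=float)
    n = x.shape[0]
    L, need = required_above(bout_length_min, fraction, epoch_length_s)
    in_bout = np.zeros(n, dtype=bool)
    if n < L:
        return in_bout
    above = x >= threshold_mg
    cs = np.concatenate([[0], np.cumsum(above)])
    # count of above epochs in (i, i+L): positions i+1 .. i+L-1
    subseq = cs[L:] - cs[1 : n - L + 2]
    qualify = above[: n - L + 1] & (subseq >= need)
    if mode == "union":
        cover = np.zeros(n + 1, dtype=np.int64)
        starts = np.flatnonzero(qualify)
        np.add.at(cover, starts, 1)
        np.add.at(cover, starts + L, -1)
        in_window = np.cumsum(cover[:-1]) > 0
        in_bout = in_window & above
    elif mode == "greedy":
        i = 0
        while i <= n - L:
            if qualify[i]:
                seg = slice(i, i + L)
                in_bout[seg] = above[seg]
                i += L
            else:
                i += 1
    else:
        raise ValueError(f"unknown bout mode {mode!r}")
    return in_bout


@dataclass
class DaySummary:
    date: pd.Timestamp
    wear_h: float
    mean_enmo_mg: float
    mvpa_min_bout5: float
    mvpa_min_bout10: float
    bin_minutes: np.ndarray


@dataclass
class PersonSummary:
    participant_id: str
    n_valid_days: int
    mean_enmo_mg: float
    mvpa_min_per_day_bout5: float
    mvpa_min_per_day_bout10: float
    meets_30min: bool
    nonwear_fraction: float
    eligible: bool = True

    def as_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "n_valid_days": self.n_valid_days,
            "mean_enmo_mg": self.mean_enmo_mg,
            "mvpa_min_per_day_bout5": self.mvpa_min_per_day_bout5,
            "mvpa_min_per_day_bout10": self.mvpa_min_per_day_bout10,
            "meets_30min": self.meets_30min,
            "nonwear_fraction": self.nonwear_fraction,
            "eligible": self.eligible,
        }


def _complete_days(es: EpochSeries) -> list[int]:
    """Calendar day indices whose full epoch grid lies inside the series."""
    spd = es.slots_per_day
    first, last = es.start_slot, es.start_slot + es.n_epochs  # [first, last)
    d0 = -(-first // spd)  # first day starting at or after the grid start
    out = []
    d = d0
    while (d + 1) * spd <= last:
        out.append(d)
        d += 1
    return out


def intensity_distribution(
    es: EpochSeries, bin_width_mg: float | None = None, cfg: PipelineConfig | None = None
) -> pd.DataFrame:
    """Minutes per intensity bin for each complete (imputed) day.

    Rows are days, columns bins [k*w, (k+1)*w) with the top bin open-ended;
    every row sums to 1440 min.
    """
    cfg = cfg or PipelineConfig()
    w = cfg.intensity_bin_width_mg if bin_width_mg is None else bin_width_mg
    days = _complete_days(es)
    spd = es.slots_per_day
    if not days:
        return pd.DataFrame()
    # one closed bin past the maximum observed value, then the open top bin
    n_bins = int(np.floor(es.enmo_mg.max() / w)) + 2 if es.n_epochs else 1
    rows = {}
    for d in days:
        a = d * spd - es.start_slot
        vals = es.enmo_mg[a : a + spd]
        idx = np.minimum((vals // w).astype(int), n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
        rows[d] = counts * es.epoch_length_s / 60.0
    cols = [f"[{k * w:g},{(k + 1) * w:g})" for k in range(n_bins - 1)]
    cols.append(f"[{(n_bins - 1) * w:g},inf)")
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = cols
    df.index = [es.day0 + pd.Timedelta(days=d) for d in days]
    return df


def _mvpa_by_day(es: EpochSeries, cfg: PipelineConfig) -> dict[int, dict[int, float]]:
    """MVPA minutes per bout length per complete day."""
    days = _complete_days(es)
    spd = es.slots_per_day
    out: dict[int, dict[int, float]] = {bl: {} for bl in cfg.bout_lengths_min}
    for bl in cfg.bout_lengths_min:
        in_bout = detect_bouts(
            es.enmo_mg, bl, cfg.mvpa_threshold_mg, cfg.bout_fraction,
            cfg.epoch_length_s, cfg.bout_mode,
        )
        for d in days:
            a = d * spd - es.start_slot
            out[bl][d] = float(in_bout[a : a + spd].sum()) * cfg.epoch_length_s / 60.0
    return out


def summarize_day(
    es: EpochSeries, day_index: int, cfg: PipelineConfig | None = None
) -> DaySummary:
    """Summary of one complete imputed day."""
    cfg = cfg or PipelineConfig()
    if day_index not in _complete_days(es):
        raise ValueError(f"day {day_index} is not a complete day of this series")
    spd = es.slots_per_day
    a = day_index * spd - es.start_slot
    sel = slice(a, a + spd)
    status = es.status_pre_impute if es.status_pre_impute is not None else es.status
    wear_h = float(
        np.isin(status[sel], [EpochStatus.VALID, EpochStatus.IMPUTED]).sum()
        * es.epoch_length_s / 3600.0
    )
    mvpa = _mvpa_by_day(es, cfg)
    bins = intensity_distribution(es, cfg=cfg)
    date = es.day0 + pd.Timedelta(days=day_index)
    return DaySummary(
        date=date,
        wear_h=wear_h,
        mean_enmo_mg=float(es.enmo_mg[sel].mean()),
        mvpa_min_bout5=mvpa[5][day_index] if 5 in mvpa else float("nan"),
        mvpa_min_bout10=mvpa[10][day_index] if 10 in mvpa else float("nan"),
        bin_minutes=bins.loc[date].to_numpy(),
    )


def summarize_person(
    es: EpochSeries,
    n_valid_days: int,
    nonwear_fraction: float = float("nan"),
    cfg: PipelineConfig | None = None,
) -> PersonSummary:
    """Person-level summary over all complete imputed 24-h cycles.

    The mean acceleration is the mean over every epoch of the included days;
    MVPA values are unweighted means of the per-day values. A participant
    with fewer than ``min_valid_days`` valid days is marked ineligible (the
    protocol's inclusion criterion) but still summarised.
    """
    cfg = cfg or PipelineConfig()
    days = _complete_days(es)
    if not days:
        raise ValueError("series contains no complete day to summarise")
    spd = es.slots_per_day
    sel = np.zeros(es.n_epochs, dtype=bool)
    for d in days:
        a = d * spd - es.start_slot
        sel[a : a + spd] = True
    mvpa = _mvpa_by_day(es, cfg)
    m5 = float(np.mean(list(mvpa[5].values()))) if 5 in mvpa else float("nan")
    m10 = float(np.mean(list(mvpa[10].values()))) if 10 in mvpa else float("nan")
    return PersonSummary(
        participant_id=es.participant_id,
        n_valid_days=n_valid_days,
        mean_enmo_mg=float(es.enmo_mg[sel].mean()),
        mvpa_min_per_day_bout5=m5,
        mvpa_min_per_day_bout10=m10,
        meets_30min=bool(m10 >= 30.0),
        nonwear_fraction=nonwear_fraction,
        eligible=n_valid_days >= cfg.min_valid_days,
    )
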