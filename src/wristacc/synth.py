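"""Synthetic raw-signal generator with exact ground truth.

Free-living wrist recordings are emulated as gravity (a unit vector in a
slowly rotating orientation) plus zero-mean band-limited activity noise plus
white sensor noise. The activity amplitude for each scheduled segment is
solved in closed form so that the expected per-sample (and hence per-epoch)
ENMO equals the segment's target: for isotropic Gaussian noise of per-axis SD
sigma added to a unit gravity vector, the vector norm R has the known 3-D
Rician-type density

    f(r) = r / (sigma sqrt(2 pi)) [exp(-(r-1)^2 / 2 sigma^2)
                                   - exp(-(r+1)^2 / 2 sigma^2)]

and E[(R - 1)^+] is obtained by quadrature; the sigma hitting a target is
found by root bracketing. Band-limiting (a 0.25-3 Hz Butterworth band-pass,
normalised to unit marginal SD) leaves the Gaussian marginal — and therefore
the expectation — unchanged, while giving the signal a plausible human-
movement autocorrelation.

Segment kinds:

- ``rest`` / ``light`` / ``mvpa``: worn, rotating orientation, activity noise
  at the segment target.
- ``sleep``: worn, low activity, plus a 30-s micro-movement burst every
  20 min so that sleep is never mistaken for non-wear (the long non-wear
  window was chosen in the protocol precisely to keep sleep out).
- ``nonwear``: one fixed random orientation per episode, sensor noise only
  (SD clamped to <= 3 mg), so the non-wear criterion holds by construction.
- ``transport``: intermittent low-amplitude motion emulating the device in
  transit before attachment / after collection; confined to the recording
  boundaries, which is what the 10 h / 20 h boundary exclusion removes.

Calibration distortion is applied last: sample' = scale * sample + offset,
then clipping to the dynamic range. Identical (schedule, distortion, seed)
inputs give bit-identical recordings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import integrate, optimize, signal

from .recording import RawRecording, SES_QUINTILES, WEIGHT_STATUSES

SEGMENT_KINDS = ("rest", "sleep", "light", "mvpa", "nonwear", "transport")

_DEFAULT_START = pd.Timestamp("2012-06-04 00:00:00")  # a Monday


class ScheduleError(ValueError):
    """Raised when an activity schedule violates its invariants."""


@dataclass(frozen=True)
class Segment:
    """One scheduled segment of a simulated day."""

    clock_start_s: float  # seconds since that day's midnight
    duration_min: float
    target_enmo_mg: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ScheduleError(f"unknown segment kind {self.kind!r}")
        if self.target_enmo_mg < 0:
            raise ScheduleError("target_enmo_mg must be >= 0")
        if self.kind == "nonwear" and self.target_enmo_mg != 0:
            raise ScheduleError("nonwear segments must have target 0")
        if not (0 <= self.clock_start_s < 86400):
            raise ScheduleError("clock_start_s must lie within the day")
        if self.duration_min <= 0:
            raise ScheduleError("duration_min must be positive")

    @property
    def duration_s(self) -> float:
        return self.duration_min * 60.0


@dataclass
class ActivitySchedule:
    """Per-day segment plans plus generator noise/orientation settings.

    ``epoch_plan[d]`` is the list of segments for simulated day ``d``; each
    day must be covered completely by non-overlapping segments.
    """

    day_count: int
    epoch_plan: list[list[Segment]]
    orientation_drift_rate: float = 0.5  # degrees per minute
    noise_sd_mg: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.day_count < 1:
            raise ScheduleError("day_count must be >= 1")
        if len(self.epoch_plan) != self.day_count:
            raise ScheduleError(
                f"epoch_plan has {len(self.epoch_plan)} day plans for day_count={self.day_count}"
            )
        for d, plan in enumerate(self.epoch_plan):
            segs = sorted(plan, key=lambda s: s.clock_start_s)
            cursor = 0.0
            for seg in segs:
                if seg.clock_start_s > cursor + 1e-9:
                    raise ScheduleError(
                        f"day {d}: gap before segment at {seg.clock_start_s} s"
                    )
                if seg.clock_start_s < cursor - 1e-9:
                    raise ScheduleError(
                        f"day {d}: overlapping segment at {seg.clock_start_s} s"
                    )
                cursor = seg.clock_start_s + seg.duration_s
            if abs(cursor - 86400.0) > 1e-6:
                raise ScheduleError(
                    f"day {d}: segments cover {cursor:.0f} s, must cover 86400 s"
                )


@dataclass(frozen=True)
class DistortionSpec:
    """Per-axis calibration distortion: sample' = scale * sample + offset (g)."""

    scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for s in self.scale:
            if not (0.8 < s < 1.2):
                raise ValueError("scale components must lie in (0.8, 1.2)")
        for o in self.offset:
            if not abs(o) < 0.1:
                raise ValueError("|offset| components must be < 0.1 g")

    @classmethod
    def identity(cls) -> "DistortionSpec":
        return cls()


@dataclass
class SyntheticTruth:
    """Exact ground truth recorded while generating a recording.

    Intervals are (start, end) in seconds since midnight of day 0.
    """

    nonwear_intervals: list[tuple[float, float]]
    mvpa_intervals: list[tuple[float, float, float]]  # (start, end, target mg)
    transport_intervals: list[tuple[float, float]]
    sleep_intervals: list[tuple[float, float]]
    distortion: DistortionSpec
    warnings: list[str] = field(default_factory=list)


# --- expected-ENMO machinery -------------------------------------------------

def expected_enmo_g(sigma: float) -> float:
    """E[max(0, ||g + e|| - 1)] for e ~ N(0, sigma^2 I_3) and ||g|| = 1."""
    if sigma <= 0:
        return 0.0
    c = 1.0 / (sigma * np.sqrt(2 * np.pi))

    def f(r):
        return (r - 1.0) * r * c * (
            np.exp(-((r - 1.0) ** 2) / (2 * sigma**2))
            - np.exp(-((r + 1.0) ** 2) / (2 * sigma**2))
        )

    val, _ = integrate.quad(f, 1.0, 1.0 + 15 * sigma, limit=200)
    return val


@lru_cache(maxsize=256)
def sigma_for_target(target_mg: float, noise_sd_mg: float = 0.0) -> float:
    """Per-axis activity SD (g) so that total noise yields the target ENMO.

    Sensor noise of SD ``noise_sd_mg`` is folded in: the returned activity SD
    satisfies sigma_act^2 + sigma_noise^2 = sigma_total^2.
    """
    target_g = target_mg / 1000.0
    noise_g = noise_sd_mg / 1000.0
    if target_g <= 0:
        return 0.0
    total = optimize.brentq(
        lambda s: expected_enmo_g(s) - target_g, 1e-9, 3.0, xtol=1e-12, rtol=8.9e-16
    )
    return float(np.sqrt(max(total**2 - noise_g**2, 0.0)))


@lru_cache(maxsize=16)
def _band_filter(rate_hz: float) -> tuple[tuple, float]:
    """Butterworth band-pass (0.25-3 Hz, upper edge clamped below Nyquist at
    low sampling rates) as second-order sections, plus its white-noise gain
    (so filtered unit-variance noise can be renormalised to unit marginal
    SD)."""
    hi = min(3.0, 0.4 * rate_hz)
    lo = min(0.25, hi / 4.0)
    sos = signal.butter(1, [lo, hi], btype="band", fs=rate_hz, output="sos")
    imp = np.zeros(1 << 14)
    imp[0] = 1.0
    h = signal.sosfilt(sos, imp)
    return tuple(map(tuple, sos)), float(np.sqrt((h**2).sum()))


def _filtered_noise(
    rng: np.random.Generator, n: int, rate_hz: float, dtype=np.float32,
    normalize: bool = True,
) -> np.ndarray:
    """(n, 3) band-limited Gaussian noise; unit marginal SD per axis when
    ``normalize`` is set (otherwise divide by the filter gain yourself)."""
    sos, gain = _band_filter(rate_hz)
    w = rng.standard_normal((n, 3), dtype=dtype)
    out = signal.sosfilt(np.asarray(sos, dtype=dtype), w, axis=0)
    if normalize:
        out /= gain
    return out


def _orientation_path(
    n: int, rate_hz: float, drift_deg_per_min: float, phase: float, dtype=np.float32
) -> np.ndarray:
    """Slowly rotating unit gravity vector: azimuth advances at the drift
    rate while elevation oscillates over +/-60 deg with a 6-h period, so a
    day of wear visits orientations on most of the sphere.

    The path is evaluated on a 1-s grid and linearly interpolated to the
    sample grid — the rotation is orders of magnitude slower than 1 Hz, so
    the interpolation error is negligible against the sensor noise."""
    duration = n / rate_hz
    grid = 10.0  # rotation is ~0.1 deg per grid step; interp error is negligible
    tc = np.arange(0.0, duration + 2 * grid, grid)
    phi = np.deg2rad(drift_deg_per_min) / 60.0 * tc + phase
    theta = np.pi / 2 + (np.pi / 3) * np.sin(2 * np.pi * tc / 21600.0 + phase)
    st = np.sin(theta)
    comps = [st * np.cos(phi), st * np.sin(phi), np.cos(theta)]
    # uniform grid: gather by repeat instead of np.interp's binary search
    bounds = np.minimum(np.ceil(tc * rate_hz - 1e-9).astype(np.int64), n)
    counts = np.diff(bounds)  # sums to n exactly
    t = np.arange(n, dtype=np.float64)
    t /= rate_hz
    frac = ((t - np.repeat(tc[:-1], counts)) / grid).astype(dtype)
    del t
    out = np.empty((n, 3), dtype=dtype)
    for k in range(3):
        c = comps[k].astype(dtype)
        lo = np.repeat(c[:-1], counts)
        out[:, k] = lo
        lo -= np.repeat(c[1:], counts)  # lo-hi
        lo *= frac
        out[:, k] -= lo
    return out


# --- generation --------------------------------------------------------------

def generate_recording(
    schedule: ActivitySchedule,
    distortion: DistortionSpec | None = None,
    *,
    sample_rate_hz: float = 85.7,
    dynamic_range_g: float = 8.0,
    start_time: pd.Timestamp = _DEFAULT_START,
    participant_id: str = "SYN001",
    dtype=np.float32,
) -> tuple[RawRecording, SyntheticTruth]:
    """Generate a raw recording and its exact ground truth.

    Samples are held in float32 by default (raw wrist devices resolve ~0.004 g,
    so single precision is generous); pass ``dtype=np.float64`` when a test
    needs tighter arithmetic.
    """
    distortion = distortion or DistortionSpec.identity()
    rng = np.random.default_rng(schedule.seed)
    total_s = schedule.day_count * 86400.0
    n = int(np.floor(total_s * sample_rate_hz - 1e-6)) + 1

    phase = rng.uniform(0, 2 * np.pi)
    grav = _orientation_path(n, sample_rate_hz, schedule.orientation_drift_rate, phase, dtype)
    amp = np.zeros(n, dtype=dtype)

    truth = SyntheticTruth([], [], [], [], distortion)
    if schedule.day_count < 2:
        truth.warnings.append(
            "recording spans fewer than 2 days; downstream validity testing "
            "cannot be satisfied"
        )

    nonwear_noise_g = min(schedule.noise_sd_mg, 3.0) / 1000.0
    noise_g = schedule.noise_sd_mg / 1000.0
    noise_scale = np.full(n, noise_g, dtype=dtype)

    def idx(lo_s: float, hi_s: float) -> slice:
        a = int(np.ceil(lo_s * sample_rate_hz - 1e-9))
        b = int(np.ceil(hi_s * sample_rate_hz - 1e-9))
        return slice(max(a, 0), min(b, n))

    for d, plan in enumerate(schedule.epoch_plan):
        for seg in sorted(plan, key=lambda s: s.clock_start_s):
            lo = d * 86400.0 + seg.clock_start_s
            hi = lo + seg.duration_s
            sl = idx(lo, hi)
            if seg.kind == "nonwear":
                v = rng.standard_normal(3)
                grav[sl] = v / np.linalg.norm(v)
                amp[sl] = 0.0
                noise_scale[sl] = nonwear_noise_g
                truth.nonwear_intervals.append((lo, hi))
                continue
            sig = sigma_for_target(seg.target_enmo_mg, schedule.noise_sd_mg)
            rel = (np.arange(sl.start, sl.stop) / sample_rate_hz - lo).astype(dtype)
            if seg.kind == "transport":
                # 60-s motion bursts every 180 s; quiet in between
                on = (rel % 180.0) < 60.0
                amp[sl] = np.where(on, sig, 0.0)
                truth.transport_intervals.append((lo, hi))
            else:
                amp[sl] = sig
                if seg.kind == "mvpa":
                    truth.mvpa_intervals.append((lo, hi, seg.target_enmo_mg))
                elif seg.kind == "sleep":
                    truth.sleep_intervals.append((lo, hi))
                    # 30-s micro-movement burst every 20 min (extra white
                    # noise, per-axis SD 40 mg) keeps sleep out of non-wear
                    burst = (rel % 1200.0) < 30.0
                    base = noise_scale[sl]
                    noise_scale[sl] = np.where(burst, np.hypot(base, 0.040), base).astype(dtype)

    # assemble in place, reusing one scratch array for both noise sources,
    # to keep peak memory at two full-size arrays
    samples = grav
    scratch = rng.standard_normal((n, 3), dtype=dtype)
    sos = np.asarray(_band_filter(sample_rate_hz)[0], dtype=dtype)
    zi = np.zeros((sos.shape[0], 2, 3), dtype=dtype)
    for a in range(0, n, 4_000_000):  # filter in place, chunked
        b = min(a + 4_000_000, n)
        scratch[a:b], zi = signal.sosfilt(sos, scratch[a:b], axis=0, zi=zi)
    amp /= _band_filter(sample_rate_hz)[1]
    scratch *= amp[:, None]
    samples += scratch
    rng.standard_normal(out=scratch, dtype=dtype)
    scratch *= noise_scale[:, None]
    samples += scratch
    del scratch
    samples *= np.asarray(distortion.scale)
    samples += np.asarray(distortion.offset, dtype=samples.dtype)
    np.clip(samples, -dynamic_range_g, dynamic_range_g, out=samples)

    rec = RawRecording(
        participant_id=participant_id,
        start_time=start_time,
        sample_rate_hz=sample_rate_hz,
        samples=samples,
        dynamic_range_g=dynamic_range_g,
    )
    if truth.warnings:
        warnings.warn(truth.warnings[0], stacklevel=2)
    return rec, truth


# --- schedule builders -------------------------------------------------------

def _hms(clock: str) -> int:
    parts = [int(p) for p in clock.split(":")]
    while len(parts) < 3:
        parts.append(0)
    h, m, s = parts
    return h * 3600 + m * 60 + s


def daily_plan(
    *,
    mvpa_start: str = "17:00",
    mvpa_minutes: float = 30.0,
    mvpa_target_mg: float = 200.0,
    sleep_target_mg: float = 3.0,
    rest_target_mg: float = 15.0,
    light_target_mg: float = 30.0,
) -> list[Segment]:
    """A plausible free-living weekday: sleep 23:00-07:00, daytime rest and
    light activity, one continuous MVPA block. Targets in mg are segment-mean
    ENMO levels typical of wrist recordings."""
    mv0 = _hms(mvpa_start)
    mv1 = mv0 + int(round(mvpa_minutes * 60))
    if not (7 * 3600 <= mv0 and mv1 <= 23 * 3600):
        raise ScheduleError("MVPA block must fall between 07:00 and 23:00")
    segs = [
        Segment(0, 7 * 60, sleep_target_mg, "sleep"),
        Segment(7 * 3600, 60, light_target_mg, "light"),
        Segment(8 * 3600, (mv0 - 8 * 3600) / 60, rest_target_mg, "rest"),
        Segment(mv0, mvpa_minutes, mvpa_target_mg, "mvpa"),
        Segment(mv1, (21 * 3600 - mv1) / 60, rest_target_mg, "rest"),
        Segment(21 * 3600, 120, light_target_mg, "light"),
        Segment(23 * 3600, 60, sleep_target_mg, "sleep"),
    ]
    return segs


def _carve(plan: list[Segment], start_s: float, end_s: float, replacement: Segment) -> list[Segment]:
    """Replace [start_s, end_s) of a day plan with one segment, trimming the
    segments it overlaps."""
    out: list[Segment] = []
    for seg in plan:
        a, b = seg.clock_start_s, seg.clock_start_s + seg.duration_s
        if b <= start_s or a >= end_s:
            out.append(seg)
            continue
        if a < start_s:
            out.append(Segment(a, (start_s - a) / 60, seg.target_enmo_mg, seg.kind))
        if b > end_s:
            out.append(Segment(end_s, (b - end_s) / 60, seg.target_enmo_mg, seg.kind))
    out.append(replacement)
    return sorted(out, key=lambda s: s.clock_start_s)


def build_schedule(
    day_count: int = 5,
    *,
    seed: int = 0,
    nonwear_episodes: list[tuple[int, str, float]] | None = None,
    with_transport: bool = True,
    transport_target_mg: float = 30.0,
    orientation_drift_rate: float = 0.5,
    noise_sd_mg: float = 2.0,
    **plan_kwargs,
) -> ActivitySchedule:
    """Standard multi-day protocol schedule.

    ``nonwear_episodes`` is a list of (day, clock_start "HH:MM", hours).
    When ``with_transport`` is set, the first 2 h of day 0 and the last 2 h of
    the final day become transport segments (inside the head/tail exclusion
    zones).
    """
    plans = [daily_plan(**plan_kwargs) for _ in range(day_count)]
    if with_transport:
        plans[0] = _carve(plans[0], 0, 2 * 3600,
                          Segment(0, 120, transport_target_mg, "transport"))
        plans[-1] = _carve(plans[-1], 22 * 3600, 86400,
                           Segment(22 * 3600, 120, transport_target_mg, "transport"))
    for day, start, hours in nonwear_episodes or []:
        s = _hms(start)
        plans[day] = _carve(plans[day], s, s + hours * 3600,
                            Segment(s, hours * 60, 0.0, "nonwear"))
    return ActivitySchedule(
        day_count=day_count,
        epoch_plan=plans,
        orientation_drift_rate=orientation_drift_rate,
        noise_sd_mg=noise_sd_mg,
        seed=seed,
    )


# --- stationary-mean simulation (calibration harness) ------------------------

def simulate_stationary_means(
    n_windows: int,
    distortion: DistortionSpec,
    noise_sd_mg: float = 2.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Window means a perfectly still device would produce under a distortion:
    unit gravity vectors uniform on the sphere, distorted, plus Gaussian noise
    on the mean."""
    rng = rng or np.random.default_rng(0)
    v = rng.standard_normal((n_windows, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    out = v * np.asarray(distortion.scale) + np.asarray(distortion.offset)
    out += rng.normal(0.0, noise_sd_mg / 1000.0, out.shape)
    return out


# --- truth serialization ------------------------------------------------------

def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Write ground truth as JSON (documented schema, schema_version 1)."""
    doc = {
        "schema_version": 1,
        "nonwear_intervals": [list(iv) for iv in truth.nonwear_intervals],
        "mvpa_intervals": [list(iv) for iv in truth.mvpa_intervals],
        "transport_intervals": [list(iv) for iv in truth.transport_intervals],
        "sleep_intervals": [list(iv) for iv in truth.sleep_intervals],
        "distortion": {
            "scale": list(truth.distortion.scale),
            "offset": list(truth.distortion.offset),
        },
        "warnings": truth.warnings,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_truth(path: str | Path) -> SyntheticTruth:
    doc = json.loads(Path(path).read_text())
    return SyntheticTruth(
        nonwear_intervals=[tuple(iv) for iv in doc["nonwear_intervals"]],
        mvpa_intervals=[tuple(iv) for iv in doc["mvpa_intervals"]],
        transport_intervals=[tuple(iv) for iv in doc["transport_intervals"]],
        sleep_intervals=[tuple(iv) for iv in doc.get("sleep_intervals", [])],
        distortion=DistortionSpec(
            scale=tuple(doc["distortion"]["scale"]),
            offset=tuple(doc["distortion"]["offset"]),
        ),
        warnings=list(doc.get("warnings", [])),
    )


# --- person-summary cohort simulation ----------------------------------------

def simulate_cohort(
    n_per_stratum: int = 100,
    *,
    seed: int = 0,
    cohort_base_mg: dict[str, float] | None = None,
    sex_effect_mg: float = 10.0,
    ses_step_mg: float = 6.0,
    person_sd_mg: float = 12.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate person summaries with planted stratum effects.

    Males get ``sex_effect_mg`` higher mean acceleration; SES quintiles carry
    a linear gradient from Q1 (highest, +2 steps) down to Q5 (-2 steps). MVPA
    minutes are generated proportionally to mean acceleration so that bout
    summaries and guideline compliance inherit the same planted ordering.
    Returns (persons, meta) frames keyed on participant_id.
    """
    rng = np.random.default_rng(seed)
    cohort_base_mg = cohort_base_mg or {"1982": 35.0, "1993": 39.0, "2004": 60.0}
    rows_p, rows_m = [], []
    pid = 0
    for cohort, base in cohort_base_mg.items():
        for sex in ("male", "female"):
            for qi, q in enumerate(SES_QUINTILES):
                mu = base + (sex_effect_mg if sex == "male" else 0.0) + (2 - qi) * ses_step_mg
                enmo = rng.normal(mu, person_sd_mg, n_per_stratum).clip(min=5.0)
                mvpa10 = (0.9 * enmo - 5 + rng.normal(0, 5, n_per_stratum)).clip(min=0.0)
                mvpa5 = mvpa10 * 1.4 + rng.normal(0, 2, n_per_stratum).clip(min=-mvpa10 * 0.2)
                weight = rng.choice(WEIGHT_STATUSES, n_per_stratum, p=[0.05, 0.55, 0.25, 0.15])
                for i in range(n_per_stratum):
                    ident = f"P{pid:05d}"
                    pid += 1
                    rows_p.append({
                        "participant_id": ident,
                        "n_valid_days": int(rng.integers(2, 8)),
                        "mean_enmo_mg": enmo[i],
                        "mvpa_min_per_day_bout5": mvpa5[i],
                        "mvpa_min_per_day_bout10": mvpa10[i],
                        "meets_30min": bool(mvpa10[i] >= 30.0),
                        "nonwear_fraction": float(rng.uniform(0, 0.05)),
                    })
                    rows_m.append({
                        "participant_id": ident,
                        "sex": sex,
                        "cohort": cohort,
                        "ses_quintile": q,
                        "weight_status": weight[i],
                    })
    return pd.DataFrame(rows_p), pd.DataFrame(rows_m)


# --- scoring helpers ----------------------------------------------------------

def interval_blocks(
    intervals: list[tuple[float, float]], block_s: float = 900.0, interior_only: bool = True
) -> set[int]:
    """Wall-clock block indices fully covered by the given intervals; with
    ``interior_only`` the first and last covered block of each interval are
    dropped (window-based detectors blur interval edges by construction)."""
    blocks: set[int] = set()
    for a, b in intervals:
        lo = int(np.ceil(a / block_s - 1e-9))
        hi = int(np.floor(b / block_s + 1e-9))
        covered = list(range(lo, hi))
        if interior_only:
            covered = covered[1:-1]
        blocks.update(covered)
    return blocks
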