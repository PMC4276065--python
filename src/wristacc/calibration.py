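"""Autocalibration against local gravity.

During stationary periods an accelerometer measures only the gravity field,
so stationary-window mean vectors should lie on the unit sphere (in g). Gain
and offset errors displace them; per-axis correction parameters are estimated
by iteratively regressing each window mean onto its closest point on the unit
sphere (the standard sphere-fit used for wrist devices), and the residual
mean absolute deviation of corrected norms from 1 g is the post-calibration
error. Files whose post-calibration error is not below 0.02 g fail the
validity gate downstream.

The fit is only applied when the stationary means cover the sphere well
enough for the problem to be well-posed: each axis must attain values below
-0.3 g and above +0.3 g (configurable). Without coverage the offsets and
gains are confounded with the mean orientation and the fit can silently
shrink the objective while corrupting the signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .recording import RawRecording

logger = logging.getLogger(__name__)


@dataclass
class CalibrationResult:
    """Per-axis correction: corrected = scale * raw + offset (g)."""

    scale: np.ndarray
    offset: np.ndarray
    error_pre_g: float
    error_post_g: float
    n_stationary: int
    sphere_coverage_ok: bool
    applied: bool
    converged: bool = True

    @classmethod
    def identity(cls, n_stationary: int = 0, error: float = float("nan")) -> "CalibrationResult":
        return cls(
            scale=np.ones(3),
            offset=np.zeros(3),
            error_pre_g=error,
            error_post_g=error,
            n_stationary=n_stationary,
            sphere_coverage_ok=False,
            applied=False,
        )

    def implied_distortion(self) -> tuple[np.ndarray, np.ndarray]:
        """The device distortion (scale, offset) this correction inverts:
        raw = d_scale * true + d_offset implies d_scale = 1 / scale and
        d_offset = -offset / scale."""
        return 1.0 / self.scale, -self.offset / self.scale


def find_stationary_windows(
    rec: RawRecording, cfg: PipelineConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Mean acceleration of all stationary windows.

    Consecutive non-overlapping windows of ``stationary_window_s`` are
    stationary when the per-axis sample SD is below the threshold (13 mg by
    default, matching the non-wear criterion) on all three axes. Returns
    (means (m, 3) in g, window start offsets in seconds since day0 midnight).
    """
    cfg = cfg or PipelineConfig()
    win = int(round(cfg.stationary_window_s * rec.sample_rate_hz))
    n_win = rec.n_samples // win
    if n_win == 0:
        return np.empty((0, 3)), np.empty(0)
    thr = cfg.stationary_sd_threshold_mg / 1000.0
    means = np.empty((n_win, 3))
    keep = np.empty(n_win, dtype=bool)
    chunk = max(1, 2_000_000 // win)
    for a in range(0, n_win, chunk):
        b = min(a + chunk, n_win)
        block = rec.samples[a * win : b * win].reshape(b - a, win, 3)
        m = block.mean(axis=1)
        sd = block.std(axis=1)
        means[a:b] = m
        keep[a:b] = (sd < thr).all(axis=1)
    starts = rec.start_offset_s + np.arange(n_win) * win / rec.sample_rate_hz
    return means[keep], starts[keep]


def _sphere_coverage(means: np.ndarray, coverage_g: float) -> bool:
    if means.shape[0] == 0:
        return False
    return bool(
        ((means.min(axis=0) < -coverage_g) & (means.max(axis=0) > coverage_g)).all()
    )


def fit_calibration(
    stationary_means: np.ndarray,
    cfg: PipelineConfig | None = None,
    *,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> CalibrationResult:
    """Fit per-axis gain/offset from stationary window means.

    Iterates: project current corrected means onto the unit sphere, then
    re-estimate each axis's (scale, offset) by least squares against the
    projections, until the mean squared norm deviation stabilises. The
    correction is only marked ``applied`` when sphere coverage holds and the
    fit did not increase the error on its own evaluation set.
    """
    cfg = cfg or PipelineConfig()
    v = np.asarray(stationary_means, dtype=float)
    if v.ndim != 2 or (v.shape[0] and v.shape[1] != 3):
        raise ValueError("stationary_means must have shape (m, 3)")
    if v.shape[0] == 0:
        return CalibrationResult.identity(0)

    norms = np.linalg.norm(v, axis=1)
    error_pre = float(np.abs(norms - 1.0).mean())
    coverage = _sphere_coverage(v, cfg.sphere_coverage_g)
    if not coverage:
        return CalibrationResult.identity(v.shape[0], error_pre)

    scale = np.ones(3)
    offset = np.zeros(3)
    prev_obj = np.inf
    converged = False
    for _ in range(max_iter):
        cur = v * scale + offset
        cn = np.linalg.norm(cur, axis=1)
        obj = float(((cn - 1.0) ** 2).mean())
        if abs(prev_obj - obj) < tol:
            converged = True
            break
        prev_obj = obj
        target = cur / cn[:, None]
        # per-axis least squares: target_k ~ a_k * v_k + b_k
        for k in range(3):
            A = np.column_stack([v[:, k], np.ones(v.shape[0])])
            coef, *_ = np.linalg.lstsq(A, target[:, k], rcond=None)
            scale[k], offset[k] = coef

    corrected = v * scale + offset
    error_post = float(np.abs(np.linalg.norm(corrected, axis=1) - 1.0).mean())
    applied = bool((scale > 0).all()) and error_post <= error_pre
    if not applied:
        logger.warning("calibration fit rejected (error_post %.4f >= error_pre %.4f)",
                       error_post, error_pre)
        scale, offset, error_post = np.ones(3), np.zeros(3), error_pre
    return CalibrationResult(
        scale=scale,
        offset=offset,
        error_pre_g=error_pre,
        error_post_g=error_post,
        n_stationary=v.shape[0],
        sphere_coverage_ok=coverage,
        applied=applied,
        converged=converged,
    )


def apply_calibration(rec: RawRecording, cal: CalibrationResult) -> RawRecording:
    """Return a calibrated copy of the recording.

    When the fit was not applied the samples pass through unchanged, but the
    recording is still flagged calibrated so downstream stages (and repeated
    calls, which are an error) can tell.
    """
    if rec.calibrated:
        raise ValueError("recording is already calibrated; refusing to apply twice")
    if cal.applied:
        samples = rec.samples * cal.scale + cal.offset
        np.clip(samples, -rec.dynamic_range_g, rec.dynamic_range_g, out=samples)
    else:
        samples = rec.samples.copy()
    return RawRecording(
        participant_id=rec.participant_id,
        start_time=rec.start_time,
        sample_rate_hz=rec.sample_rate_hz,
        samples=samples,
        dynamic_range_g=rec.dynamic_range_g,
        calibrated=True,
        sample_times_s=rec.sample_times_s,
        missing_runs=list(rec.missing_runs),
    )


def calibrate_recording(
    rec: RawRecording, cfg: PipelineConfig | None = None
) -> tuple[RawRecording, CalibrationResult]:
    """Convenience wrapper: find stationary windows, fit, apply."""
    means, _ = find_stationary_windows(rec, cfg)
    cal = fit_calibration(means, cfg)
    return apply_calibration(rec, cal), cal
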