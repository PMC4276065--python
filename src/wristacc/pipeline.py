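"""End-to-end per-participant processing.

Stage order (the status precedence the epoch flags rely on):

1. autocalibration (stationary windows -> sphere fit -> apply)
2. per-sample ENMO, 5-s wall-clock epochs (missing where coverage < 50%)
3. clipping detection -> status clipped
4. boundary exclusion (first 10 h, last 20 h) -> status excluded
5. non-wear detection on the raw signal -> status nonwear
6. validity gates (calibration error, 24-h-cycle coverage, valid days)
7. time-of-day imputation (valid files only) -> status imputed
8. day/person summaries
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .calibration import CalibrationResult, apply_calibration, find_stationary_windows, fit_calibration
from .config import PipelineConfig
from .metrics import EpochSeries, aggregate_epochs, apply_clipping, compute_enmo, detect_clipping, exclude_boundaries
from .recording import RawRecording
from .summaries import PersonSummary, summarize_person
from .wear import NonwearMask, ValidityReport, assess_validity, detect_nonwear, impute, merge_nonwear

logger = logging.getLogger(__name__)


@dataclass
class ProcessResult:
    calibration: CalibrationResult
    epochs: EpochSeries
    mask: NonwearMask
    validity: ValidityReport
    person: PersonSummary | None  # None when the file failed validity


def process_recording(rec: RawRecording, cfg: PipelineConfig | None = None) -> ProcessResult:
    cfg = cfg or PipelineConfig()
    logger.info("processing %s: %d samples at %.3f Hz (config %s)",
                rec.participant_id, rec.n_samples, rec.sample_rate_hz, cfg.digest())

    means, _ = find_stationary_windows(rec, cfg)
    cal = fit_calibration(means, cfg)
    rec_c = apply_calibration(rec, cal)
    logger.info("calibration: %d stationary windows, error %.4f -> %.4f g, applied=%s",
                cal.n_stationary, cal.error_pre_g, cal.error_post_g, cal.applied)

    enmo = compute_enmo(rec_c, cfg.enmo_truncate_negative)
    es = aggregate_epochs(rec_c, enmo, cfg)
    clip_ivals = detect_clipping(rec_c, cfg)
    es = apply_clipping(es, rec_c, clip_ivals)
    t_first = (
        float(rec_c.sample_times_s[0])
        if rec_c.sample_times_s is not None
        else rec_c.start_offset_s
    )
    es, all_excluded = exclude_boundaries(es, cfg=cfg, span_s=(t_first, rec_c.end_offset_s))
    if all_excluded:
        logger.warning("%s: recording shorter than head+tail exclusion; invalid",
                       rec.participant_id)

    mask = detect_nonwear(rec_c, cfg)
    es = merge_nonwear(es, mask)
    report = assess_validity(es, cal, cfg, mask)
    logger.info("validity: %s (slots %d/96, %d valid days)",
                report.file_valid, report.slots_covered, report.valid_days)

    person = None
    if report.file_valid:
        es = impute(es, cfg)
        person = summarize_person(
            es, report.valid_days, report.nonwear_fraction, cfg
        )
    for st, dur in es.status_durations_s().items():
        if dur:
            logger.info("  status %-8s %8.0f s", st, dur)
    return ProcessResult(cal, es, mask, report, person)
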