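import numpy as np
import pandas as pd
import pytest

import wristacc as wa
from wristacc.metrics import EpochStatus
from wristacc.wear import BlockFlag

from conftest import DAY0, make_series


def static_recording(hours=24.0, rate=20.0, noise_mg=2.0, seed=0):
    rng = np.random.default_rng(seed)
    n = int(hours * 3600 * rate)
    s = rng.normal(0, noise_mg / 1000, (n, 3)) + [0.2, -0.4, 0.89]
    return wa.RawRecording("T", DAY0, rate, s, calibrated=True)


def nonwear_oracle(rec, cfg):
    """Brute-force union-of-qualifying-windows evaluation, straight from the
    raw samples."""
    offs = rec.sample_offsets()
    t0, t_end = offs[0], rec.end_offset_s
    first_block = int(np.floor(t0 / 900))
    last_block = int(np.ceil(t_end / 900))
    flags = {}
    for b in range(first_block, last_block):
        flags[b] = BlockFlag.UNKNOWN
    for k in range(first_block - 3, last_block + 3):
        lo, hi = max(k * 900, t0), min(k * 900 + 3600, t_end)
        if hi - lo < 1800 - 1e-9:
            continue
        sel = (offs >= lo - 1e-9) & (offs < hi - 1e-9)
        blk = rec.samples[sel].astype(np.float64)
        for b in range(max(k, first_block), min(k + 4, last_block)):
            if flags[b] == BlockFlag.UNKNOWN:
                flags[b] = BlockFlag.WORN
        sd = blk.std(axis=0) * 1000
        vr = (blk.max(axis=0) - blk.min(axis=0)) * 1000
        if ((sd < cfg.nonwear_sd_threshold_mg) & (vr < cfg.nonwear_range_threshold_mg)).sum() >= 2:
            for b in range(max(k, first_block), min(k + 4, last_block)):
                flags[b] = BlockFlag.NONWEAR
    return flags


class TestDetectNonwear:
    def test_static_day_all_classifiable_blocks_nonwear(self, cfg):
        rec = static_recording()
        mask = wa.detect_nonwear(rec, cfg)
        known = mask.flags != BlockFlag.UNKNOWN
        assert known.any()
        assert (mask.flags[known] == BlockFlag.NONWEAR).all()

    def test_active_recording_no_nonwear(self, cfg):
        rng = np.random.default_rng(2)
        n = int(6 * 3600 * 20)
        s = rng.normal(0, 0.03, (n, 3)) + [0, 0, 1.0]
        rec = wa.RawRecording("T", DAY0, 20.0, s, calibrated=True)
        mask = wa.detect_nonwear(rec, cfg)
        assert (mask.flags != BlockFlag.NONWEAR).all()

    def test_embedded_gap_matches_bruteforce_oracle(self, cfg):
        rng = np.random.default_rng(3)
        rate = 20.0
        n = int(12 * 3600 * rate)
        s = rng.normal(0, 0.03, (n, 3)) + [0, 0, 1.0]
        a, b = int(4 * 3600 * rate), int(7 * 3600 * rate)  # 3-h static gap
        s[a:b] = rng.normal(0, 0.002, (b - a, 3)) + [0.3, 0.1, 0.94]
        rec = wa.RawRecording("T", DAY0, rate, s, calibrated=True)
        mask = wa.detect_nonwear(rec, cfg)
        oracle = nonwear_oracle(rec, cfg)
        got = dict(zip(mask.blocks.tolist(), [BlockFlag(f) for f in mask.flags]))
        assert got == oracle
        # interior of the 3-h gap is flagged
        for blk in range(int(4.5 * 4), int(6.5 * 4)):
            assert got[blk] == BlockFlag.NONWEAR

    def test_offgrid_start_matches_oracle(self, cfg):
        rng = np.random.default_rng(4)
        rate = 20.0
        n = int(5 * 3600 * rate)
        s = rng.normal(0, 0.03, (n, 3)) + [0, 0, 1.0]
        a, b = int(1.6 * 3600 * rate), int(3.4 * 3600 * rate)
        s[a:b] = rng.normal(0, 0.002, (b - a, 3)) + [0.1, 0.2, 0.97]
        start = DAY0 + pd.Timedelta(minutes=7, seconds=11)
        rec = wa.RawRecording("T", start, rate, s, calibrated=True)
        mask = wa.detect_nonwear(rec, cfg)
        oracle = nonwear_oracle(rec, cfg)
        got = dict(zip(mask.blocks.tolist(), [BlockFlag(f) for f in mask.flags]))
        assert got == oracle

    def test_planted_episode_recovery(self, distorted_recording, cfg):
        from wristacc.synth import interval_blocks

        rec, truth = distorted_recording
        mask = wa.detect_nonwear(rec, cfg)
        pred = set(mask.blocks[mask.flags == BlockFlag.NONWEAR].tolist())
        interior = interval_blocks(truth.nonwear_intervals)
        near = set()
        for a, b in truth.nonwear_intervals:
            near.update(range(int(a // 900) - 1, int(np.ceil(b / 900)) + 1))
        assert interior <= pred  # full recall on interior blocks
        assert not (pred - near)  # no false positives beyond edge blocks

    def test_sleep_not_flagged(self, protocol_recording, cfg):
        rec, truth = protocol_recording
        mask = wa.detect_nonwear(rec, cfg)
        assert (mask.flags != BlockFlag.NONWEAR).all()  # no non-wear scheduled


class TestValidity:
    def good_cal(self):
        cal = wa.CalibrationResult.identity()
        cal.error_pre_g = cal.error_post_g = 0.01
        return cal

    def test_full_wear_is_valid(self, cfg):
        es = make_series(n_days=5)
        rep = wa.assess_validity(es, self.good_cal(), cfg)
        assert rep.file_valid
        assert rep.slots_covered == 96
        assert rep.valid_days == 5

    def test_daily_hole_invalidates_with_92_slots(self, cfg):
        es = make_series(n_days=5)
        sod = es.seconds_of_day
        hole = (sod >= 3 * 3600) & (sod < 4 * 3600)
        es.status[hole] = EpochStatus.NONWEAR
        rep = wa.assess_validity(es, self.good_cal(), cfg)
        assert not rep.file_valid
        assert rep.slots_covered == 92

    def test_complementary_half_days_are_valid(self, cfg):
        es = make_series(n_days=2)
        sod, day = es.seconds_of_day, es.day_index
        missing = ((day == 0) & (sod >= 43200)) | ((day == 1) & (sod < 43200))
        es.status[missing] = EpochStatus.MISSING
        rep = wa.assess_validity(es, self.good_cal(), cfg)
        assert rep.file_valid  # scattered coverage over multiple days counts
        assert rep.slots_covered == 96
        assert rep.valid_days == 0  # 12 h < 16 h per day

    def test_calibration_gate(self, cfg):
        es = make_series(n_days=3)
        cal = wa.CalibrationResult.identity()
        cal.error_pre_g = cal.error_post_g = 0.025
        rep = wa.assess_validity(es, cal, cfg)
        assert not rep.file_valid
        assert any("calibration" in r for r in rep.reasons)


class TestImpute:
    def test_identity_on_fully_valid_series(self, cfg):
        es = make_series(n_days=3, fill=42.0)
        out = wa.impute(es, cfg)
        assert np.array_equal(out.enmo_mg, es.enmo_mg)
        assert (out.status == EpochStatus.VALID).all()

    def test_block_mean_example(self, cfg):
        """Invalid 15-min block at 10:00 on day 3; days 1, 2, 4, 5 hold 40,
        50, 60, 70 mg there -> imputed 55 mg."""
        es = make_series(n_days=5, fill=0.0)
        sod, day = es.seconds_of_day, es.day_index
        block = (sod >= 10 * 3600) & (sod < 10 * 3600 + 900)
        for d, v in zip([0, 1, 3, 4], [40.0, 50.0, 60.0, 70.0]):
            es.enmo_mg[block & (day == d)] = v
        es.status[block & (day == 2)] = EpochStatus.NONWEAR
        out = wa.impute(es, cfg)
        got = out.enmo_mg[block & (day == 2)]
        assert np.allclose(got, 55.0, atol=1e-12)
        assert (out.status[block & (day == 2)] == EpochStatus.IMPUTED).all()

    def test_matches_slot_mean_oracle(self, cfg):
        rng = np.random.default_rng(17)
        es = make_series(n_days=4)
        es.enmo_mg[:] = rng.uniform(0, 300, es.n_epochs)
        bad = rng.random(es.n_epochs) < 0.25
        es.status[bad] = rng.choice(
            [EpochStatus.NONWEAR, EpochStatus.CLIPPED, EpochStatus.EXCLUDED,
             EpochStatus.MISSING],
            bad.sum(),
        )
        out = wa.impute(es, cfg)
        sod = es.seconds_of_day
        valid = es.status == EpochStatus.VALID
        for i in np.flatnonzero(bad)[::97]:  # spot-check a spread of epochs
            same = valid & (sod == sod[i])
            if same.any():
                expect = es.enmo_mg[same].mean()
            else:
                blk = valid & (sod // 900 == sod[i] // 900)
                expect = es.enmo_mg[blk].mean()
            assert abs(out.enmo_mg[i] - expect) < 1e-9

    def test_idempotent_and_preserves_valid(self, cfg):
        rng = np.random.default_rng(23)
        es = make_series(n_days=3)
        es.enmo_mg[:] = rng.uniform(0, 200, es.n_epochs)
        bad = rng.random(es.n_epochs) < 0.2
        es.status[bad] = EpochStatus.NONWEAR
        once = wa.impute(es, cfg)
        twice = wa.impute(once, cfg)
        assert np.array_equal(once.enmo_mg, twice.enmo_mg)
        assert np.array_equal(once.status, twice.status)
        keep = ~bad
        assert np.array_equal(once.enmo_mg[keep], es.enmo_mg[keep])

    def test_refuses_invalid_file(self, cfg):
        es = make_series(n_days=2)
        es.status[es.seconds_of_day < 3600] = EpochStatus.MISSING  # hole on all days
        with pytest.raises(ValueError, match="invalid file"):
            wa.impute(es, cfg)
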