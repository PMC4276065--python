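import numpy as np
import pandas as pd
import pytest
from scipy.stats import special_ortho_group

import wristacc as wa
from wristacc.metrics import EpochStatus

from conftest import DAY0, make_series


def rec_from(samples, rate=10.0, start=DAY0, calibrated=True, rng_g=8.0):
    return wa.RawRecording("T", start, rate, np.asarray(samples, dtype=float),
                           dynamic_range_g=rng_g, calibrated=calibrated)


class TestEnmo:
    # closed forms: unit gravity, 3-4-5 unit norm, sub-1-g truncation,
    # norm 1.3 -> 300 mg
    CASES = [
        ((0.0, 0.0, 1.0), 0.0),
        ((0.6, 0.8, 0.0), 0.0),
        ((0.0, 0.0, 0.5), 0.0),
        ((0.3, 0.4, 1.2), 0.3),
    ]

    def test_closed_forms(self):
        rec = rec_from([c for c, _ in self.CASES])
        enmo = wa.compute_enmo(rec)
        expected = np.array([e for _, e in self.CASES])
        assert np.abs(enmo - expected).max() < 1e-12

    def test_negative_values_truncated_to_zero(self):
        rec = rec_from([(0, 0, 0.5)])
        assert wa.compute_enmo(rec)[0] == 0.0
        assert wa.compute_enmo(rec, truncate_negative=False)[0] == -0.5

    def test_rotation_invariance(self):
        rng = np.random.default_rng(11)
        v = rng.uniform(-1.5, 1.5, (200, 3))
        base = wa.compute_enmo(rec_from(v))
        for R in special_ortho_group.rvs(3, size=100, random_state=7):
            rot = wa.compute_enmo(rec_from(v @ R.T))
            assert np.abs(rot - base).max() < 1e-12


class TestClipping:
    def test_moderate_signal_unflagged(self):
        rng = np.random.default_rng(0)
        rec = rec_from(rng.uniform(-4, 4, (5000, 3)))
        assert wa.detect_clipping(rec) == []

    def test_sustained_pinned_run_flagged(self):
        s = np.zeros((1000, 3))
        s[:, 2] = 1.0
        s[200:500, 0] = 8.0  # 30 s at 10 Hz
        rec = rec_from(s)
        assert wa.detect_clipping(rec) == [(200, 500)]

    def test_isolated_spike_not_sustained(self):
        s = np.zeros((1000, 3))
        s[:, 2] = 1.0
        s[300:302, 0] = 7.9
        rec = rec_from(s)
        assert wa.detect_clipping(rec) == []

    def test_matches_run_length_oracle(self):
        rng = np.random.default_rng(5)
        s = np.zeros((20000, 3))
        s[:, 2] = 1.0
        # random high runs of varied length
        pos = 0
        truth = []
        while pos < 19000:
            run = int(rng.integers(1, 300))
            if rng.random() < 0.3:
                s[pos : pos + run, 1] = 7.8
                truth.append((pos, min(pos + run, 20000)))
            pos += run + int(rng.integers(50, 200))
        rec = rec_from(s)
        min_len = int(np.ceil(10.0 * rec.sample_rate_hz))
        expected = [iv for iv in truth if iv[1] - iv[0] >= min_len]
        assert wa.detect_clipping(rec) == expected

    def test_clipped_epochs_marked(self):
        s = np.zeros((6000, 3))
        s[:, 2] = 1.0
        s[1200:1500, 0] = 8.0
        rec = rec_from(s)
        es = wa.aggregate_epochs(rec, wa.compute_enmo(rec))
        es2 = wa.apply_clipping(es, rec, wa.detect_clipping(rec))
        clipped = np.flatnonzero(es2.status == EpochStatus.CLIPPED)
        # samples 1200-1500 at 10 Hz = seconds 120-150 = epochs 24-29
        assert list(clipped) == list(range(24, 30))


class TestAggregation:
    def test_constant_signal_constant_epochs(self):
        n = 36000  # 1 h at 10 Hz
        s = np.tile([0.3, 0.4, 1.2], (n, 1))
        rec = rec_from(s)
        es = wa.aggregate_epochs(rec, wa.compute_enmo(rec))
        assert es.n_epochs == 720
        assert np.allclose(es.enmo_mg, 300.0, atol=1e-9)
        assert (es.status == EpochStatus.VALID).all()

    def test_alignment_to_wall_clock(self):
        start = DAY0 + pd.Timedelta(seconds=2)
        rec = wa.RawRecording("T", start, 10.0, np.tile([0, 0, 1.0], (600, 1)),
                              calibrated=True)
        es = wa.aggregate_epochs(rec, wa.compute_enmo(rec))
        # first epoch starts at 00:00:05
        assert es.start_slot * es.epoch_length_s == 5

    def test_epoch_means_match_bruteforce_windower(self):
        rng = np.random.default_rng(21)
        rate = 7.3  # awkward non-integer rate
        n = 5000
        rec = wa.RawRecording("T", DAY0, rate,
                              rng.uniform(-1, 1, (n, 3)).clip(-1, 1) + [0, 0, 0.5],
                              calibrated=True)
        enmo = wa.compute_enmo(rec)
        es = wa.aggregate_epochs(rec, enmo)
        offs = rec.sample_offsets()
        for k in range(es.n_epochs):
            lo = (es.start_slot + k) * es.epoch_length_s
            sel = (offs >= lo - 1e-12) & (offs < lo + es.epoch_length_s - 1e-12)
            if sel.sum():
                assert abs(es.enmo_mg[k] - enmo[sel].mean() * 1000) < 1e-9

    def test_concatenation_commutes(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(-0.2, 0.2, (7200, 3)) + [0, 0, 1.0]
        rec = rec_from(s)
        es_full = wa.aggregate_epochs(rec, wa.compute_enmo(rec))
        half = 3600  # samples; 360 s = epoch boundary at 10 Hz
        rec_a = rec_from(s[:half])
        rec_b = wa.RawRecording("T", DAY0 + pd.Timedelta(seconds=360), 10.0,
                                s[half:], calibrated=True)
        es_a = wa.aggregate_epochs(rec_a, wa.compute_enmo(rec_a))
        es_b = wa.aggregate_epochs(rec_b, wa.compute_enmo(rec_b))
        joined = np.concatenate([es_a.enmo_mg, es_b.enmo_mg])
        assert np.abs(joined - es_full.enmo_mg).max() < 1e-9


class TestBoundaryExclusion:
    def test_week_long_recording_retains_138_hours(self):
        es = make_series(n_epochs=168 * 720)  # 168 h of 5-s epochs
        out, all_excluded = wa.exclude_boundaries(es, 10, 20)
        assert not all_excluded
        kept_h = (out.status == EpochStatus.VALID).sum() * 5 / 3600
        assert kept_h == 138.0

    def test_24h_recording_fully_excluded(self):
        es = make_series(n_days=1)
        out, all_excluded = wa.exclude_boundaries(es, 10, 20)
        assert all_excluded
        assert (out.status == EpochStatus.EXCLUDED).all()

    def test_transport_segments_fall_inside_exclusion(self, protocol_recording, cfg):
        rec, truth = protocol_recording
        es = wa.aggregate_epochs(rec, wa.compute_enmo(rec), cfg)
        out, _ = wa.exclude_boundaries(es, cfg=cfg)
        slots_s = out.slots * out.epoch_length_s
        for a, b in truth.transport_intervals:
            inside = (slots_s >= a) & (slots_s < b)
            assert (out.status[inside] == EpochStatus.EXCLUDED).all()

    def test_status_durations_conserved(self):
        es = make_series(n_days=2)
        out, _ = wa.exclude_boundaries(es, 10, 20)
        assert sum(out.status_durations_s().values()) == 2 * 86400
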