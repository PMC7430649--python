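"""Trace filtering, bp conversion and event segmentation."""

import numpy as np
import pytest

from badmotor.polymer import duplex_rise_per_bp
from badmotor.simulate import Trace, build_profile, simulate_trace
from badmotor.pipeline import analyze_trace
from badmotor.traces import (
    SegmentationConfig,
    arrest_positions,
    downsample_filter,
    segment_events,
    summarize_events,
    z_to_bp,
)

RISE8 = duplex_rise_per_bp(8.0)


def make_trace(pos_fn, duration=120.0, noise_sd=0.0, seed=0, force=8.0,
               baseline=2200.0):
    """60 Hz trace from a bp-position function of time (looping geometry)."""
    t = np.arange(int(duration * 60)) / 60.0
    pos = pos_fn(t)
    rng = np.random.default_rng(seed)
    z = baseline - pos * RISE8
    if noise_sd:
        z = z + rng.normal(0, noise_sd, t.size)
    return Trace(times=t, z=z, force=force, profile_name="fixture",
                 sampling_rate=60.0, baseline_z=baseline)


def ramp(t0, length, rate, down_rate=1e7):
    def fn(t):
        pos = np.clip((t - t0) * rate, 0, length)
        t_peak = t0 + length / rate
        after = t >= t_peak
        pos[after] = np.clip(length - (t[after] - t_peak) * down_rate, 0,
                             None)
        return pos
    return fn


class TestDownsample:
    def test_constant_input_preserved(self):
        tr = make_trace(lambda t: np.zeros_like(t), duration=10.0)
        p = downsample_filter(tr, 3.0)
        assert np.allclose(p.values, 2200.0)
        assert p.rate == pytest.approx(3.0)

    def test_alternating_signal_averages_to_zero(self):
        t = np.arange(1200) / 60.0
        z = np.where(np.arange(1200) % 2 == 0, 1.0, -1.0)
        tr = Trace(times=t, z=z, force=8.0, profile_name="x",
                   sampling_rate=60.0)
        p = downsample_filter(tr, 3.0)
        assert np.allclose(p.values, 0.0)

    def test_white_noise_sd_shrinks_by_sqrt_window(self):
        rng = np.random.default_rng(0)
        n = 20 * 10_000
        t = np.arange(n) / 60.0
        sigma = 15.0
        tr = Trace(times=t, z=rng.normal(0, sigma, n), force=8.0,
                   profile_name="x", sampling_rate=60.0)
        p = downsample_filter(tr, 3.0)
        assert p.values.std() == pytest.approx(sigma / np.sqrt(20), rel=0.15)

    def test_target_rate_must_be_lower(self):
        tr = make_trace(lambda t: np.zeros_like(t), duration=5.0)
        with pytest.raises(ValueError):
            downsample_filter(tr, 120.0)


class TestZToBp:
    def test_baseline_maps_to_zero(self):
        tr = make_trace(lambda t: np.zeros_like(t), duration=10.0)
        p = z_to_bp(downsample_filter(tr), force=8.0)
        assert np.allclose(p.values, 0.0, atol=1e-9)

    def test_known_height_drop_converts_through_wlc(self):
        # dz = -320 nm at 8 pN -> 320 / rise(8 pN) bp of forward motion
        tr = make_trace(lambda t: np.zeros_like(t), duration=10.0)
        tr.z[300:] -= 320.0
        p = z_to_bp(downsample_filter(tr), force=8.0, baseline_z=2200.0)
        assert p.values[-1] == pytest.approx(320.0 / RISE8, rel=1e-9)

    def test_round_trip_on_noiseless_simulated_trace(self):
        from dataclasses import replace
        from badmotor.simulate import NoiseModel
        prof = replace(build_profile("LOW30"),
                       noise=NoiseModel(z_noise_sd=0.0))
        tr = simulate_trace(prof, 1200.0, seed=7)
        p = z_to_bp(downsample_filter(tr), force=8.0,
                    baseline_z=tr.baseline_z)
        true60 = (tr.baseline_z - tr.z) / RISE8
        n = p.values.size
        true3 = true60[:n * 20].reshape(n, 20).mean(axis=1)
        assert np.abs(p.values - true3).max() < 1.0

    def test_rejects_nonpositive_force(self):
        tr = make_trace(lambda t: np.zeros_like(t), duration=10.0)
        with pytest.raises(ValueError):
            z_to_bp(downsample_filter(tr), force=0.0)


class TestSegmentation:
    def test_clean_ramp_yields_one_event_with_exact_stats(self):
        tr = make_trace(ramp(30.0, 1000.0, 200.0))
        p = z_to_bp(downsample_filter(tr), force=8.0, baseline_z=2200.0)
        events, dwells, rehybs = segment_events(p)
        assert len(events) == 1
        assert events[0].length == pytest.approx(1000.0, rel=0.02)
        assert events[0].mean_rate == pytest.approx(200.0, rel=0.02)
        assert not events[0].pauses and not events[0].backslides

    def test_partial_retreat_detected_as_incomplete_backslide(self):
        def fn(t):
            pos = np.zeros_like(t)
            seg1 = (t >= 30) & (t < 33)
            pos[seg1] = (t[seg1] - 30) * 200
            plateau = 600.0
            seg2 = (t >= 33) & (t < 33.075)  # 150 bp retreat at 2000 bp/s
            pos[seg2] = plateau - (t[seg2] - 33) * 2000
            seg3 = (t >= 33.075) & (t < 33.7)  # restart delay
            pos[seg3] = 450.0
            seg4 = (t >= 33.7) & (t < 35.45)
            pos[seg4] = 450.0 + (t[seg4] - 33.7) * 200
            t5 = 35.45
            seg5 = t >= t5
            pos[seg5] = np.clip(800.0 - (t[seg5] - t5) * 2000, 0, None)
            return pos
        tr = make_trace(fn)
        p = z_to_bp(downsample_filter(tr), force=8.0, baseline_z=2200.0)
        events, _, _ = segment_events(p)
        assert len(events) == 1
        assert len(events[0].backslides) == 1
        bs = events[0].backslides[0]
        assert not bs.complete
        assert bs.depth == pytest.approx(150.0, abs=60.0)

    def test_flat_noisy_trace_produces_no_false_events(self):
        tr = make_trace(lambda t: np.zeros_like(t), duration=3600.0,
                        noise_sd=15.0, seed=3)
        p = z_to_bp(downsample_filter(tr), force=8.0)
        events, dwells, rehybs = segment_events(p)
        assert events == []

    def test_short_or_empty_trace_returns_empty_lists(self):
        tr = make_trace(lambda t: np.zeros_like(t), duration=0.05)
        p = z_to_bp(downsample_filter(tr), force=8.0)
        assert segment_events(p) == ([], [], [])

    def test_ground_truth_detection_rate_and_length_error(self):
        # >= 90% of comfortably-detectable generative events (>= 2x the
        # minimum event length) are found, each within 10% of true length
        prof = build_profile("LOW30")
        cfg = SegmentationConfig()
        found, match = 0, 0
        for seed in (21, 22):
            tr = simulate_trace(prof, 3600.0, seed=seed)
            events, _, _, _ = analyze_trace(tr)
            truth = [e for e in tr.truth if e.type == "unwinding"
                     and e.bp_end >= 2 * cfg.min_event_length
                     and e.t_end < 3500.0]
            for u in truth:
                found += 1
                for ev in events:
                    if ev.t_start < u.t_end and ev.t_end > u.t_start and \
                            abs(ev.length - u.bp_end) <= 0.10 * u.bp_end:
                        match += 1
                        break
        assert found >= 60
        assert match / found >= 0.90

    def test_event_count_monotone_in_thresholds(self):
        prof = build_profile("LOW30")
        tr = simulate_trace(prof, 3600.0, seed=31)
        p = z_to_bp(downsample_filter(tr), force=8.0)
        counts_v = []
        for v_min in (30.0, 60.0, 90.0):
            ev, _, _ = segment_events(p, SegmentationConfig(v_min=v_min))
            counts_v.append(len(ev))
        assert counts_v == sorted(counts_v, reverse=True)
        counts_l = []
        for mel in (100.0, 300.0, 600.0):
            ev, _, _ = segment_events(
                p, SegmentationConfig(min_event_length=mel))
            counts_l.append(len(ev))
        assert counts_l == sorted(counts_l, reverse=True)

    def test_pauses_inside_parent_and_backslides_bounded(self, low30):
        for ev in low30.events:
            for pz in ev.pauses:
                assert ev.t_start <= pz.t_start <= pz.t_end <= ev.t_end
            for bs in ev.backslides:
                # trough noise below baseline allows up to baseline_tol slack
                assert bs.depth <= ev.max_position + 50.0

    def test_dwell_bookkeeping_conservation(self, low30):
        # at most (#events - 1) dwells per tether
        from collections import Counter
        ev_count = Counter(e.trace_id for e in low30.events)
        dw_count = Counter(d.trace_id for d in low30.dwells)
        for tid, n in dw_count.items():
            assert n <= ev_count[tid] - 1 + 1  # +1 slack for marker splits

    def test_truncated_events_excluded_from_distributions(self, low30):
        assert all(e.terminated_by != "trace-end"
                   for e in low30.clean_events)
        assert len(low30.clean_events) <= len(low30.events)


class TestSummaries:
    def test_empty_input_gives_zero_counts(self):
        s = summarize_events([])
        assert s.n_events == 0 and s.pct_backslide == 0.0

    def test_single_event_arrest_position(self):
        # an arrested motor stalls at its maximum before the tether recovers
        def fn(t):
            pos = np.clip((t - 30.0) * 200.0, 0, 500.0)
            after = t >= 34.5  # 2 s stall at 500 bp, then fast recovery
            pos[after] = np.clip(500.0 - (t[after] - 34.5) * 2000.0, 0, None)
            return pos
        tr = make_trace(fn)
        p = z_to_bp(downsample_filter(tr), force=8.0, baseline_z=2200.0)
        events, _, _ = segment_events(p)
        pos = arrest_positions(events)
        assert pos.shape == (1,)
        assert pos[0] == pytest.approx(500.0, rel=0.05)
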