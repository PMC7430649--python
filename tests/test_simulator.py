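"""The stochastic motor simulator: profiles, event statistics, geometry."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import stats

from badmotor.polymer import duplex_rise_per_bp
from badmotor.simulate import (
    MotorKinetics,
    Nick,
    PROFILE_NAMES,
    TetherDesign,
    build_profile,
    entry_rate_from_fraction,
    simulate_event_lengths,
    simulate_trace,
)


class TestProfiles:
    def test_low30_values(self):
        p = build_profile("LOW30")
        assert p.kinetics.unwind_rate_mean == 215.0
        assert p.kinetics.mean_event_length == 900.0
        assert p.initiation.protein_conc == pytest.approx(30e-9)
        assert p.initiation.mean_waiting == pytest.approx(61.0)

    def test_high163_values(self):
        p = build_profile("HIGH163")
        assert p.kinetics.unwind_rate_mean == 159.0
        assert p.kinetics.mean_event_length == 1181.0
        assert p.initiation.mean_waiting == pytest.approx(11.6)

    def test_unknown_name_rejected_with_valid_list(self):
        with pytest.raises(ValueError, match="LOW30"):
            build_profile("XYZ")

    @pytest.mark.parametrize("name", PROFILE_NAMES)
    def test_all_profiles_build_and_are_frozen(self, name):
        p = build_profile(name)
        assert p.force > 0
        with pytest.raises(Exception):
            p.force = 99.0  # frozen dataclass

    def test_entry_rate_conversion_identity(self):
        # f = r*tau/(1+r*tau) inverted: converting back recovers f
        for f in (0.05, 0.24, 0.41):
            r = entry_rate_from_fraction(f, 4.2)
            assert r * 4.2 / (1 + r * 4.2) == pytest.approx(f)


class TestEventLengths:
    def test_single_draw_nonnegative(self):
        k = MotorKinetics(detach_per_bp=1.0)
        assert simulate_event_lengths(k, 1, seed=0)[0] >= 0

    def test_sample_mean_within_3_se(self):
        k = MotorKinetics(detach_per_bp=1 / 900.0)
        x = simulate_event_lengths(k, 10_000, seed=1)
        assert abs(x.mean() - 900.0) < 3 * 900.0 / np.sqrt(10_000)

    def test_nick_truncates_at_jittered_arrest(self):
        tether = TetherDesign(nick=Nick("top", 2000.0, 100.0))
        k = MotorKinetics(detach_per_bp=1 / 900.0)
        x = simulate_event_lengths(k, 5000, seed=2, tether=tether)
        assert x.max() <= 2000.0 + 3 * 100.0 + 1e-9

    def test_ks_against_generative_exponential(self):
        k = MotorKinetics(detach_per_bp=1 / 900.0)
        x = simulate_event_lengths(k, 5000, seed=3)
        stat, p = stats.kstest(x, "expon", args=(0, 900.0))
        assert p > 0.01

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            simulate_event_lengths(MotorKinetics(), 0, seed=0)


class TestTraceSimulation:
    def test_no_initiation_gives_flat_trace(self):
        p = build_profile("LOW30")
        tr = simulate_trace(p, 120.0, seed=0, initiation_rate_override=0.0)
        se = p.noise.z_noise_sd / np.sqrt(tr.z.size)
        assert abs(tr.z.mean() - tr.baseline_z) < 3 * se

    def test_deterministic_for_identical_seed(self):
        p = build_profile("HIGH163")
        a = simulate_trace(p, 300.0, seed=7)
        b = simulate_trace(p, 300.0, seed=7)
        assert np.array_equal(a.z, b.z)
        assert a.truth[-1] == b.truth[-1]

    def test_different_seeds_differ(self):
        p = build_profile("HIGH163")
        a = simulate_trace(p, 300.0, seed=7)
        b = simulate_trace(p, 300.0, seed=8)
        assert not np.array_equal(a.z, b.z)

    def test_sampling_grid_uniform_at_60hz(self):
        tr = simulate_trace(build_profile("LOW30"), 10.0, seed=0)
        assert tr.times.size == 600
        assert np.allclose(np.diff(tr.times), 1 / 60.0)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            simulate_trace(build_profile("LOW30"), -5.0, seed=0)

    def test_initiation_waiting_times_match_kon(self):
        # pooled over traces: exponential with mean 1/(kon*[protein])
        p = build_profile("HIGH163")
        waits = []
        for seed in range(3):
            tr = simulate_trace(p, 3600.0, seed=seed)
            inits = sorted(e.t_start for e in tr.truth
                           if e.type == "initiation")
            ends = sorted(e.t_end for e in tr.truth
                          if e.type == "rehybridization")
            j = 0
            for r in ends:
                while j < len(inits) and inits[j] <= r:
                    j += 1
                if j < len(inits):
                    waits.append(inits[j] - r)
        assert len(waits) >= 200
        assert np.mean(waits) == pytest.approx(p.initiation.mean_waiting,
                                               rel=0.10)

    def test_track_conservation_bounds_height_change(self):
        p = build_profile("LOW30")
        tr = simulate_trace(p, 3600.0, seed=11)
        max_dz = tr.baseline_z - tr.z.min()
        bound = p.tether.track_length * duplex_rise_per_bp(p.force) \
            + 6 * p.noise.z_noise_sd
        assert max_dz <= bound

    def test_truth_positions_within_track(self):
        p = build_profile("LOW30")
        tr = simulate_trace(p, 3600.0, seed=12)
        for e in tr.truth:
            assert 0.0 <= e.bp_start <= p.tether.track_length + 1e-6
            assert 0.0 <= e.bp_end <= p.tether.track_length + 1e-6

    def test_nicktop_truth_bounded_by_nick(self):
        p = build_profile("NICKTOP")
        nick = p.tether.nick
        tr = simulate_trace(p, 3600.0, seed=13)
        for e in tr.truth:
            if e.type == "unwinding":
                assert e.bp_end <= nick.position + 3 * nick.jitter_sd + 1e-6

    def test_nickbot_translocation_passes_nick_without_release(self):
        p = build_profile("NICKBOT")
        tr = simulate_trace(p, 7200.0, seed=14)
        maxima = [e.bp_end for e in tr.truth if e.type == "unwinding"]
        assert max(maxima) > p.tether.nick.position
        # tether never released: the trace always returns near baseline
        assert tr.z.max() < tr.baseline_z + 6 * p.noise.z_noise_sd

    def test_canonical_geometry_sign_flips_at_crossover(self):
        p = build_profile("CANONICAL")
        hi = simulate_trace(p, 1200.0, seed=15)
        lo = simulate_trace(replace(p, force=4.0), 1200.0, seed=15)
        # above ~6 pN unwinding lengthens the tether; below it shortens
        assert (hi.z.max() - hi.baseline_z) > (hi.baseline_z - hi.z.min())
        assert (lo.baseline_z - lo.z.min()) > (lo.z.max() - lo.baseline_z)

    def test_mean_event_length_without_pauses_or_backslides(self):
        # empirical mean of ground-truth event lengths ~ 1/detach_per_bp
        p = build_profile("LOW30")
        kin = replace(p.kinetics, pause_entry_rate=0.0, backslide_rate=0.0)
        p = replace(p, kinetics=kin)
        lengths = []
        seed = 0
        while len(lengths) < 1000:
            tr = simulate_trace(p, 7200.0, seed=seed)
            lengths += [e.bp_end for e in tr.truth if e.type == "unwinding"]
            seed += 1
        m = np.mean(lengths)
        assert m == pytest.approx(900.0, rel=0.05)


class TestTetherValidation:
    def test_nick_outside_track_rejected(self):
        with pytest.raises(ValueError):
            TetherDesign(nick=Nick("top", 9000.0))

    def test_loading_site_inside_insert(self):
        with pytest.raises(ValueError):
            TetherDesign(loading_site_offset=7000.0)

    def test_bad_nick_strand_rejected(self):
        with pytest.raises(ValueError):
            Nick("middle", 100.0)
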