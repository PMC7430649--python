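#!/usr/bin/env python
"""Simulate bead-height traces for every study condition.

For each named condition this simulates an hour of recording and writes the
ground-truth event log under results/traces/; for the reference condition
(LOW30) a 30 s raw-trace excerpt is written as well so the 60 Hz file format
is concrete.  Full-length raw traces are multi-megabyte and regenerable from
(profile, seed), so they are not stored; the statistical drivers re-simulate
in memory.
"""

import logging
from pathlib import Path

from badmotor import io as bio
from badmotor.simulate import PROFILE_NAMES, Trace, build_profile, \
    simulate_trace

logging.basicConfig(level=logging.WARNING)

OUT = Path(__file__).resolve().parents[1] / "results" / "traces"
OUT.mkdir(parents=True, exist_ok=True)

SEED = 2020

for name in PROFILE_NAMES:
    profile = build_profile(name)
    trace = simulate_trace(profile, duration=3600.0, seed=SEED)
    stem = OUT / name.lower()
    bio.write_truth(trace.truth, stem.with_name(stem.name + "_truth.csv"))
    n_events = sum(1 for e in trace.truth if e.type == "unwinding")
    print(f"{name:9s} 1 h at {profile.force:g} pN, "
          f"[protein] {profile.initiation.protein_conc*1e9:.0f} nM: "
          f"{n_events} unwinding events -> {stem.name}_truth.csv")
    if name == "LOW30":
        n = int(30 * trace.sampling_rate)
        excerpt = Trace(times=trace.times[:n], z=trace.z[:n],
                        force=trace.force, profile_name=trace.profile_name,
                        sampling_rate=trace.sampling_rate, seed=SEED,
                        baseline_z=trace.baseline_z)
        bio.write_trace(excerpt, stem.with_suffix(".tsv"))
        print(f"          30 s raw excerpt -> {stem.name}.tsv")

print(f"\nground truth written under {OUT}")
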