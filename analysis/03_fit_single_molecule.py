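#!/usr/bin/env python
"""Fit the single-molecule distributions and the association rate constant.

Reads the event/dwell tables written by 02_segment_events.py, fits the
event-length exponentials, the Gaussian/Gamma rate models and the dwell
exponentials per condition, then recovers kon from the hyperbolic
dependence of the mean initiation waiting time on protein concentration.
Writes results/single_molecule_fits.csv and results/kon_fit.csv.
"""

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from badmotor.fits import fit_dwell_hyperbola
from badmotor.pipeline import run_condition
from badmotor.simulate import InitiationModel

logging.basicConfig(level=logging.WARNING)

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 2021  # same conditions as 02_segment_events.py

CONDITIONS = {"LOW30": 350, "MED50": 600, "HIGH163": 500}

rows = []
for name, min_events in CONDITIONS.items():
    res = run_condition(name, seed=SEED, min_events=min_events)
    lf = res.fit_lengths()
    gauss, gamma, preferred = res.fit_rates()
    df = res.fit_dwells()
    print(f"{name}: <L> = {lf.params['mean']:.0f} +/- "
          f"{lf.stderr['mean']:.0f} bp (n={lf.n}); "
          f"rate {gauss.params['mean']:.0f} bp/s (gaussian) / "
          f"{gamma.params['mean']:.0f} bp/s (gamma, preferred: {preferred}); "
          f"<dt> = {df.params['mean']:.1f} +/- {df.stderr['mean']:.1f} s "
          f"(n={df.n})")
    for fit, quantity in ((lf, "length_bp"), (gauss, "rate_gaussian_bps"),
                          (gamma, "rate_gamma_bps"), (df, "dwell_s")):
        rows.append({"condition": name, "quantity": quantity,
                     "model": fit.model, "mean": fit.params["mean"],
                     "stderr": fit.stderr["mean"], "n": fit.n,
                     "r_squared": fit.r_squared})

pd.DataFrame(rows).to_csv(ROOT / "single_molecule_fits.csv", index=False)

# kon from initiation waiting times at the three concentrations
rng = np.random.default_rng(SEED)
concs = np.array([30e-9, 50e-9, 163e-9])
means = [InitiationModel(protein_conc=c).sample_waiting_times(300, rng).mean()
         for c in concs]
fit = fit_dwell_hyperbola(concs, means)
kon, se = fit.params["kon"], fit.stderr["kon"]
print(f"\nkon = {kon:.3g} +/- {se:.2g} M^-1 s^-1 "
      f"(hyperbolic fit of mean dwell vs [protein])")
pd.DataFrame([{"kon_M_s": kon, "stderr": se,
               "concentrations_nM": "30,50,163", "dwells_per_conc": 300}]
             ).to_csv(ROOT / "kon_fit.csv", index=False)
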