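#!/usr/bin/env python
"""Bulk enzymology: ATPase Michaelis-Menten and ssDNA-activation fits,
streptavidin-displacement and helicase progress curves, iron stoichiometry.

Generates synthetic assay datasets at the installed generative parameters
(3% multiplicative noise for rate assays, 5% for gel-based time courses),
fits each, and writes results/bulk_fits.csv plus results/bulk_datasets/.
"""

import logging
import warnings
from pathlib import Path

import pandas as pd

from badmotor.bulk import (a535_for_stoichiometry, bulk_profile,
                           fit_activation, fit_michaelis_menten,
                           fit_progress_curve, generate_bulk_dataset,
                           iron_per_protein)

logging.basicConfig(level=logging.WARNING)
warnings.filterwarnings("ignore", category=RuntimeWarning)

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "bulk_datasets"
DATA.mkdir(parents=True, exist_ok=True)
SEED = 2023

JOBS = [
    ("mm", "atpase_mm", 0.03, fit_michaelis_menten, ("kcat", "Km")),
    ("activation", "dna_activation", 0.03, fit_activation,
     ("basal_rate", "Vmax", "K_DNA")),
    ("progress", "displacement_progress", 0.05, fit_progress_curve,
     ("amplitude", "kobs")),
    ("progress", "helicase_wt_progress", 0.05, fit_progress_curve,
     ("amplitude", "kobs")),
    ("progress", "helicase_3prime_progress", 0.05, fit_progress_curve,
     ("amplitude", "kobs")),
]

rows = []
for i, (kind, profile, cv, fitfn, names) in enumerate(JOBS):
    params = bulk_profile(profile)
    d = generate_bulk_dataset(kind, params, replicates=3, noise_cv=cv,
                              seed=SEED + i)
    d.table.to_csv(DATA / f"{profile}.csv", index=False)
    fit = fitfn(d)
    report = ", ".join(f"{k} = {fit.params[k]:.3g} +/- {fit.stderr[k]:.2g}"
                       for k in names)
    print(f"{profile:26s} {report}  (R2 = {fit.r_squared:.4f})")
    for k in names:
        rows.append({"assay": profile, "parameter": k,
                     "value": fit.params[k], "stderr": fit.stderr[k],
                     "r_squared": fit.r_squared})

# iron stoichiometry: synthetic A535 constructed for 3 Fe per protein
a535 = a535_for_stoichiometry(3.0)
ratio = iron_per_protein(a535)
print(f"\niron assay: A535 = {a535:.4f} -> {ratio:.2f} mol Fe / mol protein")
rows.append({"assay": "iron_chelation", "parameter": "fe_per_protein",
             "value": ratio, "stderr": 0.0, "r_squared": float("nan")})

pd.DataFrame(rows).to_csv(ROOT / "bulk_fits.csv", index=False)
print("fits -> results/bulk_fits.csv")
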