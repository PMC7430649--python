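"""Bulk enzymology: ATPase Michaelis-Menten and ssDNA-activation fits,
single-exponential progress curves, iron stoichiometry, and the synthetic
dataset generator for all three assay kinds.

The three assay kinds are:

``mm``
    steady-state ATPase rate v([ATP]) = kcat*[S]/(Km+[S]) at saturating
    ssDNA cofactor;
``activation``
    ATPase rate versus ssDNA cofactor concentration (in nucleotides),
    v([DNA]) = basal + (Vmax-basal)*[DNA]/(K_DNA+[DNA]);
``progress``
    fraction of product versus time for gel-based displacement/unwinding
    assays, fraction(t) = A*(1-exp(-kobs*t)).

Rates are per-enzyme turnovers (s^-1); conversion from raw absorbance slopes
is assumed done upstream.  The iron assay converts a bathophenanthroline
A535 reading to mol Fe per mol protein through Beer-Lambert and the assay's
dilution scheme.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from badmotor.fits import FitResult

__all__ = [
    "BulkDataset",
    "KineticParams",
    "IronAssayConfig",
    "bulk_profile",
    "BULK_PROFILES",
    "fit_michaelis_menten",
    "fit_activation",
    "fit_progress_curve",
    "iron_per_protein",
    "generate_bulk_dataset",
]

_KINDS = ("mm", "activation", "progress")


@dataclass
class KineticParams:
    """Kinetic parameter bundle (only the fields relevant to a kind are set).

    kcat, basal_rate, Vmax in s^-1; Km in uM ATP; K_DNA in uM nucleotides;
    kobs in min^-1; amplitude a fraction in [0, 1].
    """

    kcat: float | None = None
    Km: float | None = None
    basal_rate: float | None = None
    Vmax: float | None = None
    K_DNA: float | None = None
    kobs: float | None = None
    amplitude: float | None = None

    def __post_init__(self) -> None:
        for name in ("kcat", "Km", "basal_rate", "Vmax", "K_DNA", "kobs",
                     "amplitude"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.amplitude is not None and self.amplitude > 1:
            raise ValueError("amplitude is a fraction in [0, 1]")


@dataclass
class BulkDataset:
    """A concentration-rate or time-fraction table.

    ``table`` has columns x, y, replicate; x is concentration (uM for mm and
    activation) or time (min for progress), y is rate (s^-1) or fraction.
    """

    kind: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        missing = {"x", "y", "replicate"} - set(self.table.columns)
        if missing:
            raise ValueError(f"table missing columns {sorted(missing)}")
        if (self.table["x"] < 0).any():
            raise ValueError("x values must be >= 0")
        if self.kind == "progress" and (
                (self.table["y"] < -0.05).any() or (self.table["y"] > 1.05).any()):
            raise ValueError("progress fractions must lie in [0, 1] (5% slack)")

    @property
    def x(self) -> np.ndarray:
        return self.table["x"].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.table["y"].to_numpy(float)


# Generative truths for the bulk assays, used by the synthetic generator.
# mm/activation: 10 nM enzyme, saturating cofactor; progress kinds: gel-based
# time courses over 4 min.
BULK_PROFILES: dict[str, KineticParams] = {
    "atpase_mm": KineticParams(kcat=101.0, Km=223.0),
    "dna_activation": KineticParams(basal_rate=1.0, Vmax=101.0, K_DNA=1.66),
    "displacement_progress": KineticParams(kobs=0.48, amplitude=0.9),
    "helicase_wt_progress": KineticParams(kobs=0.66, amplitude=0.9),
    "helicase_3prime_progress": KineticParams(kobs=0.05, amplitude=0.9),
}


def bulk_profile(name: str) -> KineticParams:
    """Return a copy of a built-in bulk kinetic parameter bundle."""
    try:
        return replace(BULK_PROFILES[name])
    except KeyError:
        raise ValueError(
            f"unknown bulk profile {name!r}; valid names: "
            f"{sorted(BULK_PROFILES)}") from None


def _mm_model(s, kcat, km):
    return kcat * s / (km + s)


def _activation_model(d, basal, vmax, kdna):
    return basal + (vmax - basal) * d / (kdna + d)


def _progress_model(t, amplitude, kobs):
    return amplitude * (1.0 - np.exp(-kobs * t))


def _mult_sigma(y: np.ndarray) -> np.ndarray:
    """Relative weights for the multiplicative (constant-CV) error model of
    coupled-assay and gel-quantification noise: sd proportional to signal,
    floored at 10% of the largest signal so zero-signal points keep finite
    weight."""
    return np.maximum(np.abs(y), 0.1 * np.abs(y).max() if y.size else 1.0)


def _fit_report(model_name, x, y, popt, pcov, names) -> FitResult:
    pred = {
        "michaelis_menten": lambda: _mm_model(x, *popt),
        "activation": lambda: _activation_model(x, *popt),
        "progress": lambda: _progress_model(x, *popt),
    }[model_name]()
    resid = y - pred
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else \
        np.full(len(popt), np.nan)
    sig2 = max(ss_res / len(x), np.finfo(float).tiny)
    loglik = float(-0.5 * len(x) * (np.log(2 * np.pi * sig2) + 1.0))
    return FitResult(model=model_name,
                     params={k: float(v) for k, v in zip(names, popt)},
                     stderr={k: float(abs(e)) for k, e in zip(names, perr)},
                     log_likelihood=loglik, r_squared=min(r2, 1.0),
                     n=int(len(x)))


def fit_michaelis_menten(d: BulkDataset) -> FitResult:
    """Nonlinear least squares of v = kcat*[S]/(Km+[S]).

    Needs >= 4 distinct substrate concentrations; if the data do not span
    the fitted Km a warning is emitted (wide standard errors), not an error.
    """
    if d.kind != "mm":
        raise ValueError(f"expected a 'mm' dataset, got {d.kind!r}")
    x, y = d.x, d.y
    if np.unique(x).size < 4:
        raise ValueError("Michaelis-Menten fit needs >= 4 distinct [S]")
    p0 = (float(y.max()) or 1.0, float(np.median(x[x > 0])) or 1.0)
    popt, pcov = curve_fit(_mm_model, x, y, p0=p0, sigma=_mult_sigma(y),
                           maxfev=20000)
    res = _fit_report("michaelis_menten", x, y, popt, pcov, ("kcat", "Km"))
    if res.params["Km"] > x.max() or res.params["Km"] < x[x > 0].min():
        warnings.warn(
            "substrate range does not span the fitted Km; parameter errors "
            "will be wide", RuntimeWarning, stacklevel=2)
    return res


def fit_activation(d: BulkDataset) -> FitResult:
    """Fit v = basal + (Vmax-basal)*[DNA]/(K_DNA+[DNA]).

    Requires a zero-DNA point (which anchors the basal rate).  If every DNA
    concentration is zero the fit degenerates to the basal rate alone and is
    flagged in ``extras['degenerate']``.
    """
    if d.kind != "activation":
        raise ValueError(f"expected an 'activation' dataset, got {d.kind!r}")
    x, y = d.x, d.y
    if not np.any(x == 0):
        raise ValueError("activation fit requires a zero-DNA point")
    if np.all(x == 0):
        basal = float(y.mean())
        res = FitResult(model="activation",
                        params={"basal_rate": basal, "Vmax": basal,
                                "K_DNA": float("nan")},
                        stderr={"basal_rate": float(y.std(ddof=1) / np.sqrt(len(y)))
                                if len(y) > 1 else 0.0,
                                "Vmax": 0.0, "K_DNA": 0.0},
                        log_likelihood=0.0, r_squared=0.0, n=len(x),
                        extras={"degenerate": 1.0})
        warnings.warn("all-zero DNA column: only the basal rate is defined",
                      RuntimeWarning, stacklevel=2)
        return res
    p0 = (float(y[x == 0].mean()), float(y.max()),
          float(np.median(x[x > 0])))
    popt, pcov = curve_fit(_activation_model, x, y, p0=p0,
                           sigma=_mult_sigma(y), maxfev=20000)
    return _fit_report("activation", x, y, popt, pcov,
                       ("basal_rate", "Vmax", "K_DNA"))


def fit_progress_curve(d: BulkDataset) -> FitResult:
    """Fit fraction(t) = A*(1 - exp(-kobs*t)); t in minutes, kobs in min^-1.

    Needs >= 5 timepoints including t = 0.  Gross non-monotone outliers
    (points more than 0.25 below the running maximum) are flagged in
    ``extras['n_outliers']`` but retained in the fit.
    """
    if d.kind != "progress":
        raise ValueError(f"expected a 'progress' dataset, got {d.kind!r}")
    x, y = d.x, d.y
    if np.unique(x).size < 5:
        raise ValueError("progress-curve fit needs >= 5 timepoints")
    if not np.any(x == 0):
        raise ValueError("progress-curve fit requires a t = 0 point")
    order = np.argsort(x, kind="stable")
    run_max = np.maximum.accumulate(y[order])
    n_out = int(np.sum(run_max - y[order] > 0.25))
    if n_out:
        warnings.warn(f"{n_out} gross non-monotone outlier(s) in progress "
                      "curve", RuntimeWarning, stacklevel=2)
    span = float(x.max()) or 1.0
    p0 = (max(float(y.max()), 0.1), 2.0 / span)
    popt, pcov = curve_fit(_progress_model, x, y, p0=p0,
                           sigma=_mult_sigma(y), maxfev=20000)
    res = _fit_report("progress", x, y, popt, pcov, ("amplitude", "kobs"))
    res.extras["n_outliers"] = float(n_out)
    return res


@dataclass(frozen=True)
class IronAssayConfig:
    """Bathophenanthroline iron assay geometry and extinction coefficients.

    The default dilution scheme: 10 ul of protein stock denatured with 3 ul
    HCl and neutralised with 130 ul Tris, giving ~143 ul of assay volume in
    which both the released iron and the protein are diluted.
    """

    epsilon_535: float = 22369.0  # M^-1 cm^-1, Fe(II)-bathophenanthroline
    path_length: float = 1.0  # cm
    protein_volume_ul: float = 10.0
    assay_volume_ul: float = 143.0
    protein_stock_uM: float = 15.0
    protein_epsilon_280: float = 195960.0  # M^-1 cm^-1 (theoretical)

    def __post_init__(self) -> None:
        for name in ("epsilon_535", "path_length", "protein_volume_ul",
                     "assay_volume_ul", "protein_stock_uM",
                     "protein_epsilon_280"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive, got {v!r}")
        if self.assay_volume_ul < self.protein_volume_ul:
            raise ValueError("assay volume cannot be below protein volume")


def iron_per_protein(a535: float, cfg: IronAssayConfig | None = None) -> float:
    """Mol Fe per mol protein from an A535 bathophenanthroline reading.

    [Fe] in the assay follows Beer-Lambert, [Fe] = A535/(eps535 * path); the
    protein concentration in the assay is the stock concentration scaled by
    the dilution, and the stoichiometry is their ratio (iron and protein are
    diluted identically, so the dilution cancels only in the protein term's
    favour - both are referred to the final assay volume).
    """
    if cfg is None:
        cfg = IronAssayConfig()
    a535 = float(a535)
    if not math.isfinite(a535) or a535 < 0:
        raise ValueError(f"a535 must be finite and >= 0, got {a535!r}")
    fe_assay_M = a535 / (cfg.epsilon_535 * cfg.path_length)
    protein_assay_M = (cfg.protein_stock_uM * 1e-6
                       * cfg.protein_volume_ul / cfg.assay_volume_ul)
    if protein_assay_M <= 0:
        raise ValueError("protein concentration in the assay is zero")
    return fe_assay_M / protein_assay_M


def a535_for_stoichiometry(fe_per_protein: float,
                           cfg: IronAssayConfig | None = None) -> float:
    """Inverse of :func:`iron_per_protein`: the A535 a given stoichiometry
    would produce.  Useful for constructing synthetic assay readings."""
    if cfg is None:
        cfg = IronAssayConfig()
    protein_assay_M = (cfg.protein_stock_uM * 1e-6
                       * cfg.protein_volume_ul / cfg.assay_volume_ul)
    return fe_per_protein * protein_assay_M * cfg.epsilon_535 * cfg.path_length


# Default measurement designs.  MM: 8 ATP points log-spaced over the measured
# 0.05-2 mM range (in uM); activation: 8 DNA points from 0 to 20 uM nt
# (~10x K_DNA); progress: 8 points over a 4 min time course.
_DEFAULT_DESIGNS = {
    "mm": np.geomspace(50.0, 2000.0, 8),
    "activation": np.concatenate([[0.0], np.geomspace(0.25, 20.0, 7)]),
    "progress": np.concatenate([[0.0], np.geomspace(0.25, 4.0, 7)]),
}


def default_design(kind: str) -> np.ndarray:
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
    return _DEFAULT_DESIGNS[kind].copy()


def generate_bulk_dataset(kind: str, params: KineticParams,
                          design=None, replicates: int = 3,
                          noise_cv: float = 0.03,
                          seed: int | None = 0) -> BulkDataset:
    """Synthetic bulk dataset: model curve times multiplicative lognormal noise.

    The lognormal noise has unit mean and coefficient of variation
    ``noise_cv`` (mimicking coupled-assay and gel-quantification error);
    the dataset is deterministic for a fixed ``seed``.
    """
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    x = np.asarray(default_design(kind) if design is None else design, float)
    if kind == "mm":
        if params.kcat is None or params.Km is None:
            raise ValueError("mm generation needs kcat and Km")
        curve = _mm_model(x, params.kcat, params.Km)
    elif kind == "activation":
        if None in (params.basal_rate, params.Vmax, params.K_DNA):
            raise ValueError("activation generation needs basal_rate, Vmax, K_DNA")
        curve = _activation_model(x, params.basal_rate, params.Vmax,
                                  params.K_DNA)
    else:
        if params.kobs is None:
            raise ValueError("progress generation needs kobs")
        amp = 0.9 if params.amplitude is None else params.amplitude
        curve = _progress_model(x, amp, params.kobs)

    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        if noise_cv > 0:
            sigma = np.sqrt(np.log1p(noise_cv ** 2))
            noise = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma,
                                  size=x.size)
        else:
            noise = np.ones(x.size)
        y = curve * noise
        if kind == "progress":
            y = np.clip(y, 0.0, 1.0)
        rows.append(pd.DataFrame({"x": x, "y": y, "replicate": rep}))
    return BulkDataset(kind=kind, table=pd.concat(rows, ignore_index=True))
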