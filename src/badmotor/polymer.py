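"""Polymer elasticity of dsDNA and ssDNA, and bead-fluctuation force calibration.

This module supplies the single nm<->bp conversion used by the rest of the
pipeline.  Double-stranded DNA follows the extensible Marko-Siggia worm-like
chain interpolation

    F = (kBT/P) * [ 1/(4 (1 - x/Lc + F/S)^2) - 1/4 + x/Lc - F/S ]

solved numerically for the fractional extension x/Lc at a given force F, with
persistence length P, stretch modulus S and thermal energy kBT.  Single
stranded DNA follows a freely-jointed chain with Kuhn length b and contour
length per nucleotide c:

    x/nt = c * [ coth(F b / kBT) - kBT / (F b) ]

With the default parameters the extension per residue of ssDNA crosses that
of dsDNA near 6 pN: above the crossover ssDNA is longer than duplex, below it
it is shorter.  This regime boundary is what distinguishes a canonical
unwinding geometry (bead height tracks the ss-ds extension difference) from
the looping geometry in which translocated DNA is fed into a protein-bound
loop and the bead height simply decreases by the distance translocated.

Force calibration uses the equipartition (Brownian fluctuation) estimator
F = kBT * <z> / var(x) on the lateral excursions of a tethered bead.

All lengths are in nm, forces in pN and energies in pN*nm throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

#: Boltzmann constant in pN nm / K.
KB = 0.0138065

__all__ = [
    "KB",
    "DuplexElasticity",
    "SsDnaElasticity",
    "ThermalContext",
    "duplex_fractional_extension",
    "duplex_rise_per_bp",
    "ssdna_extension_per_nt",
    "force_from_fluctuations",
]


@dataclass(frozen=True)
class DuplexElasticity:
    """Worm-like chain parameters for double-stranded DNA.

    Defaults are the standard values for B-form DNA in physiological salt:
    persistence length 50 nm, contour rise 0.34 nm/bp, stretch modulus
    1000 pN, room temperature 296 K.
    """

    persistence_length: float = 50.0  # nm
    contour_rise: float = 0.34  # nm per bp
    stretch_modulus: float = 1000.0  # pN
    temperature: float = 296.0  # K

    def __post_init__(self) -> None:
        for name in ("persistence_length", "contour_rise", "stretch_modulus",
                     "temperature"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v!r}")
        if self.contour_rise > 0.4:
            raise ValueError(
                f"contour_rise {self.contour_rise} nm/bp exceeds 0.4 nm/bp")

    @property
    def kBT(self) -> float:
        return KB * self.temperature


@dataclass(frozen=True)
class SsDnaElasticity:
    """Freely-jointed chain parameters for single-stranded DNA.

    Defaults (Kuhn length 1.5 nm, contour 0.56 nm/nt) place the ss/ds
    extension-per-residue crossover near 6 pN.
    """

    kuhn_length: float = 1.5  # nm
    contour_per_nt: float = 0.56  # nm per nt
    temperature: float = 296.0  # K

    def __post_init__(self) -> None:
        for name in ("kuhn_length", "contour_per_nt", "temperature"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v!r}")

    @property
    def kBT(self) -> float:
        return KB * self.temperature


@dataclass(frozen=True)
class ThermalContext:
    """Thermal energy kBT (pN nm) derived from an absolute temperature."""

    temperature: float = 296.0  # K
    kBT: float = field(init=False)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.temperature) and self.temperature > 0):
            raise ValueError(f"temperature must be positive, got {self.temperature!r}")
        object.__setattr__(self, "kBT", KB * self.temperature)


def _check_force(force: float) -> float:
    force = float(force)
    if not math.isfinite(force) or force < 0:
        raise ValueError(f"force must be finite and >= 0 pN, got {force!r}")
    return force


def duplex_fractional_extension(force: float,
                                e: DuplexElasticity | None = None) -> float:
    """Fractional extension x/Lc of dsDNA at `force` (pN).

    Solves the extensible Marko-Siggia interpolation by bracketed root
    finding (absolute tolerance 1e-6 on the fractional extension).  Returns a
    value in [0, 1.05]; forces so large that the interpolation would stretch
    the molecule beyond 5% past contour are rejected rather than clamped.
    """
    force = _check_force(force)
    if e is None:
        e = DuplexElasticity()
    if force == 0.0:
        return 0.0
    kBT, P, S = e.kBT, e.persistence_length, e.stretch_modulus

    def resid(x: float) -> float:
        ell = x - force / S  # inextensible part of the extension
        return (kBT / P) * (0.25 / (1.0 - ell) ** 2 - 0.25 + ell) - force

    lo = 0.0
    hi = 1.0 + force / S - 1e-12
    if resid(lo) > 0 or resid(hi) < 0:
        raise ArithmeticError(
            f"failed to bracket the WLC solution at {force} pN")
    x = brentq(resid, lo, hi, xtol=1e-6)
    if x > 1.05:
        raise ArithmeticError(
            f"WLC extension {x:.3f} at {force} pN outside the validity "
            "range [0, 1.05] of the interpolation")
    return float(x)


def duplex_rise_per_bp(force: float, e: DuplexElasticity | None = None) -> float:
    """Apparent rise per base pair (nm/bp) of dsDNA held at `force` (pN).

    This is the conversion constant between bead-height change and base
    pairs translocated at a fixed force.
    """
    if e is None:
        e = DuplexElasticity()
    return e.contour_rise * duplex_fractional_extension(force, e)


def ssdna_extension_per_nt(force: float,
                           e: SsDnaElasticity | None = None) -> float:
    """Extension per nucleotide (nm/nt) of ssDNA at `force` (pN), FJC model."""
    force = _check_force(force)
    if e is None:
        e = SsDnaElasticity()
    if force == 0.0:
        return 0.0
    u = force * e.kuhn_length / e.kBT
    # Langevin function, series expansion below u ~ 1e-4 for stability
    if u < 1e-4:
        langevin = u / 3.0 - u ** 3 / 45.0
    else:
        langevin = 1.0 / math.tanh(u) - 1.0 / u
    return e.contour_per_nt * langevin


def force_from_fluctuations(lateral_variance: float, tether_extension: float,
                            t: ThermalContext | None = None) -> float:
    """Equipartition force estimate F = kBT * <z> / var(x) (pN).

    `lateral_variance` is the variance (nm^2) of the bead's lateral
    excursions and `tether_extension` the mean tether extension (nm).
    """
    if t is None:
        t = ThermalContext()
    lateral_variance = float(lateral_variance)
    tether_extension = float(tether_extension)
    if not math.isfinite(lateral_variance) or lateral_variance <= 0:
        raise ValueError(
            "lateral_variance must be positive (zero variance implies "
            f"infinite force), got {lateral_variance!r}")
    if not math.isfinite(tether_extension) or tether_extension <= 0:
        raise ValueError(
            f"tether_extension must be positive, got {tether_extension!r}")
    return t.kBT * tether_extension / lateral_variance


def ssdna_dsdna_crossover_force(duplex: DuplexElasticity | None = None,
                                ssdna: SsDnaElasticity | None = None,
                                lo: float = 1.0, hi: float = 20.0) -> float:
    """Force (pN) at which ssDNA extension per nt equals dsDNA rise per bp.

    Above the returned force ssDNA is the longer polymer per residue; below
    it the duplex is longer.  With the module defaults this lies near 6 pN.
    """
    duplex = duplex or DuplexElasticity()
    ssdna = ssdna or SsDnaElasticity()

    def diff(f: float) -> float:
        return ssdna_extension_per_nt(f, ssdna) - duplex_rise_per_bp(f, duplex)

    if diff(lo) > 0 or diff(hi) < 0:
        raise ArithmeticError(
            f"no ss/ds crossover bracketed in [{lo}, {hi}] pN")
    return float(brentq(diff, lo, hi, xtol=1e-4))


def lateral_variance_at_force(force: float, tether_extension: float,
                              t: ThermalContext | None = None) -> float:
    """Expected lateral bead variance (nm^2) for a tether at `force` (pN)."""
    if t is None:
        t = ThermalContext()
    force = _check_force(force)
    if force == 0:
        raise ValueError("lateral variance diverges at zero force")
    return t.kBT * tether_extension / force
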