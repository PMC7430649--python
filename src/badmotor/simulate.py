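"""Stochastic state-machine simulation of a ssDNA-loop-extruding DNA motor
observed as bead height versus time in magnetic tweezers.

The simulated enzyme loads at a 5' ssDNA flap on a ~6.6 kb tether and
translocates 5'->3' while extruding the non-translocated strand as a ssDNA
loop.  In this looping geometry the bead height decreases by exactly the
distance translocated (in bp, converted through the worm-like-chain rise per
base pair at the applied force) regardless of the force regime.  The state
machine is

    waiting --initiation--> unwinding <--> (pause | backslide)
            --detachment--> rehybridization --> waiting

with exponential waiting times throughout: initiation at rate kon*[protein];
detachment at a constant per-bp probability (exponential event lengths of
mean <L>); pauses and backslides entered as Poisson processes during
unwinding; rehybridization running at a fast fixed rate back to baseline.
Event bookkeeping is exact in continuous time (Gillespie-style breakpoints)
and only afterwards sampled onto the 60 Hz camera grid with additive
Gaussian bead noise; there is no per-frame Euler stepping.

Per-event phenomenon frequencies printed as percentages (the fraction of
events containing at least one pause or backslide) are converted to Poisson
entry rates using the exact relation for exponentially distributed exposure
times: if a fraction f of events of mean duration tau contain at least one
entry at rate r, then f = r*tau/(1 + r*tau), hence

    r = f / ((1 - f) * tau).

Named profiles freeze the study conditions (protein concentration, motor
speed, processivity, dwell time, pause/backslide frequencies, nicked-tether
variants, SSB co-incubation, canonical-geometry comparison).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from badmotor.polymer import (
    DuplexElasticity,
    SsDnaElasticity,
    ThermalContext,
    duplex_rise_per_bp,
    lateral_variance_at_force,
    ssdna_extension_per_nt,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Nick",
    "TetherDesign",
    "MotorKinetics",
    "InitiationModel",
    "NoiseModel",
    "SsbMode",
    "ExperimentProfile",
    "GroundTruthEvent",
    "Trace",
    "PROFILE_NAMES",
    "build_profile",
    "simulate_trace",
    "simulate_event_lengths",
]


@dataclass(frozen=True)
class Nick:
    """A site-specific single-strand break.

    ``strand`` is 'top' (the translocated strand; arrests the motor) or
    'bottom' (the looped strand; transparent to translocation).  ``position``
    is in bp downstream of the loading site; ``jitter_sd`` is the Gaussian
    spread (bp) of the apparent arrest position.
    """

    strand: str
    position: float
    jitter_sd: float = 100.0

    def __post_init__(self) -> None:
        if self.strand not in ("top", "bottom"):
            raise ValueError(f"nick strand must be 'top' or 'bottom', "
                             f"got {self.strand!r}")
        if self.position <= 0:
            raise ValueError("nick position must be > 0 bp")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


@dataclass(frozen=True)
class TetherDesign:
    """Geometry of the magnetic-tweezers DNA tether.

    A ~6.6 kb insert carries a 37-nt poly-dT 5' flap (the loading site)
    445 bp from the surface-anchored end; the track available for
    translocation runs from the loading site toward the bead-proximal end.
    """

    insert_length: float = 6600.0  # bp
    loading_site_offset: float = 445.0  # bp from the surface-anchored end
    flap_length: float = 37.0  # nt
    track_length: float = 6155.0  # bp
    nick: Optional[Nick] = None

    def __post_init__(self) -> None:
        if not 0 < self.loading_site_offset < self.insert_length:
            raise ValueError("loading site must lie inside the insert")
        if not 0 < self.track_length <= self.insert_length:
            raise ValueError("track_length must be positive and bounded by "
                             "the insert")
        if self.track_length > self.insert_length - self.loading_site_offset + 1e-9:
            raise ValueError("track cannot extend past the bead-proximal end")
        if self.nick is not None and not (0 < self.nick.position
                                          < self.track_length):
            raise ValueError("nick position must lie within the track")


@dataclass(frozen=True)
class MotorKinetics:
    """Kinetic parameters of the translocating motor.

    Rates are per second, lengths in bp.  ``detach_per_bp`` is the constant
    per-bp detachment probability, so event lengths are exponential with
    mean 1/detach_per_bp.  Pause durations are a shifted exponential
    (minimum ``pause_min_duration``, mean ``pause_mean_duration``), keeping
    pauses resolvable at the 3 Hz analysis bandwidth.  A backslide replaces
    unwinding with fast rehybridization to a depth that is complete (back to
    baseline) with probability ``backslide_complete_fraction`` and otherwise
    uniform in 10-90% of the current progress, then restarts after
    ``backslide_restart_delay``.

    ``pause_entry_rate`` and ``backslide_rate`` are quoted in s^-1 at the
    mean unwinding rate but realised as per-bp hazards
    (rate / unwind_rate_mean), i.e. entries are Poisson along the distance
    translocated.  This keeps the per-event pause/backslide frequencies
    independent of the event's own drawn speed, matching the observation
    that backslide frequency is constant across conditions with different
    mean rates.  ``rate_floor`` truncates the per-event Gaussian rate
    spread at the segmentation velocity threshold: slower motors are
    unobservable in this assay and do not contribute to the printed rate
    distributions.
    """

    unwind_rate_mean: float = 215.0  # bp/s
    unwind_rate_cv: float = 0.5
    detach_per_bp: float = 1.0 / 900.0  # 1/bp
    pause_entry_rate: float = 0.0  # s^-1 during unwinding at the mean rate
    pause_mean_duration: float = 3.0  # s
    pause_min_duration: float = 1.5  # s
    rehyb_rate: float = 2000.0  # bp/s
    rehyb_pause_entry_rate: float = 0.0  # s^-1 during rehybridization
    backslide_rate: float = 0.0  # s^-1 during unwinding
    backslide_complete_fraction: float = 0.0
    backslide_restart_delay: float = 0.5  # s
    arrest_stall_mean: float = 2.0  # s stalled at a top-strand nick
    rate_floor: float = 30.0  # bp/s lower truncation of per-event rates

    def __post_init__(self) -> None:
        for name in ("unwind_rate_mean", "detach_per_bp", "rehyb_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("unwind_rate_cv", "pause_entry_rate",
                     "pause_mean_duration", "pause_min_duration",
                     "rehyb_pause_entry_rate", "backslide_rate",
                     "backslide_restart_delay", "arrest_stall_mean",
                     "rate_floor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.backslide_complete_fraction <= 1:
            raise ValueError("backslide_complete_fraction must be in [0, 1]")
        if self.pause_mean_duration < self.pause_min_duration:
            raise ValueError("pause_mean_duration must be >= pause_min_duration")

    @property
    def mean_event_length(self) -> float:
        return 1.0 / self.detach_per_bp


def entry_rate_from_fraction(fraction: float, mean_duration: float) -> float:
    """Poisson entry rate giving `fraction` of exponentially-long exposures
    (mean `mean_duration`) at least one entry: r = f / ((1-f) * tau)."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    if mean_duration <= 0:
        raise ValueError("mean_duration must be > 0")
    return fraction / ((1.0 - fraction) * mean_duration)


@dataclass(frozen=True)
class InitiationModel:
    """Second-order initiation: waiting times exponential with mean
    1/(kon * [protein])."""

    kon: float = 5.9e5  # M^-1 s^-1
    protein_conc: float = 30e-9  # M

    def __post_init__(self) -> None:
        if self.kon <= 0 or self.protein_conc <= 0:
            raise ValueError("kon and protein_conc must be > 0")

    @property
    def mean_waiting(self) -> float:
        return 1.0 / (self.kon * self.protein_conc)

    def sample_waiting_times(self, n: int, seed=None) -> np.ndarray:
        """Draw n initiation waiting times (s)."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        return rng.exponential(self.mean_waiting, size=int(n))


@dataclass(frozen=True)
class NoiseModel:
    """Camera sampling and bead-height noise.

    The default 15 nm per 60 Hz sample leaves ~3.4 nm of noise after
    filtering to 3 Hz, i.e. roughly 10 bp - well below the 100 bp minimum
    event size used in segmentation.
    """

    sampling_rate: float = 60.0  # Hz
    z_noise_sd: float = 15.0  # nm per raw sample
    drift_rate: float = 0.0  # nm/s

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.z_noise_sd < 0:
            raise ValueError("z_noise_sd must be >= 0")


@dataclass(frozen=True)
class SsbMode:
    """Single-stranded DNA binding protein co-incubation.

    SSB coats the extruded ssDNA: rehybridization (including backslide
    retreats) slows by ``rehyb_slowdown`` and the backslide entry rate is
    multiplied by ``backslide_suppression``.
    """

    rehyb_slowdown: float = 20.0
    backslide_suppression: float = 0.275

    def __post_init__(self) -> None:
        if self.rehyb_slowdown < 1:
            raise ValueError("rehyb_slowdown must be >= 1")
        if not 0 <= self.backslide_suppression <= 1:
            raise ValueError("backslide_suppression must be in [0, 1]")


@dataclass(frozen=True)
class ExperimentProfile:
    """Named bundle of tether design, motor kinetics, initiation, noise,
    force and geometry defining one study condition."""

    name: str
    tether: TetherDesign
    kinetics: MotorKinetics
    initiation: InitiationModel
    noise: NoiseModel
    force: float = 8.0  # pN
    geometry: str = "looping"  # or "canonical"
    ssb_mode: Optional[SsbMode] = None
    duplex: DuplexElasticity = field(default_factory=DuplexElasticity)
    ssdna: SsDnaElasticity = field(default_factory=SsDnaElasticity)

    def __post_init__(self) -> None:
        if self.force <= 0:
            raise ValueError("force must be > 0 pN")
        if self.geometry not in ("looping", "canonical"):
            raise ValueError("geometry must be 'looping' or 'canonical'")

    @property
    def nm_per_bp(self) -> float:
        """Signed bead-height change per bp translocated (nm; positive = down
        for the looping geometry, signed by the ss/ds difference for the
        canonical geometry)."""
        rise = duplex_rise_per_bp(self.force, self.duplex)
        if self.geometry == "looping":
            return rise
        return -(ssdna_extension_per_nt(self.force, self.ssdna) - rise)


@dataclass
class GroundTruthEvent:
    """Benchmark label for one simulated state interval."""

    type: str  # unwinding | rehybridization | pause | backslide | initiation
    t_start: float
    t_end: float
    bp_start: float
    bp_end: float
    complete: Optional[bool] = None
    phase: Optional[str] = None  # for pauses: unwinding | rehybridization
    rate: Optional[float] = None  # for unwinding: the event's drawn bp/s


@dataclass
class Trace:
    """A sampled bead trajectory with optional ground truth."""

    times: np.ndarray  # s, uniform at 1/sampling_rate
    z: np.ndarray  # nm
    force: float  # pN
    profile_name: str
    sampling_rate: float
    seed: Optional[int] = None
    truth: Optional[list[GroundTruthEvent]] = None
    lateral: Optional[np.ndarray] = None  # nm, for force calibration
    baseline_z: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.z = np.asarray(self.z, float)
        if self.times.shape != self.z.shape:
            raise ValueError("times and z must have the same shape")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.sampling_rate, rtol=1e-4):
                raise ValueError("times must be uniform at 1/sampling_rate")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z must be finite")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.times.size else 0.0


# ---------------------------------------------------------------------------
# Built-in profiles.  Percentages are per-event frequencies of the study
# conditions; the dwell means at 30 and 163 nM pin the per-profile effective
# initiation rate.  MED50 speed/processivity interpolate between the printed
# flanking conditions (only its pause/backslide statistics are printed).

_PROFILE_SPECS: dict[str, dict] = {
    "LOW30": dict(conc=30e-9, v=215.0, cv=0.5, L=900.0, dwell=61.0,
                  pause_u=0.05, pause_r=0.22, backslide=0.24, complete=0.97),
    "MED50": dict(conc=50e-9, v=190.0, cv=0.5, L=1040.0, dwell=None,
                  pause_u=0.10, pause_r=0.41, backslide=0.21, complete=0.52),
    "HIGH163": dict(conc=163e-9, v=159.0, cv=0.5, L=1181.0, dwell=11.6,
                    pause_u=0.21, pause_r=0.37, backslide=0.27, complete=0.58),
}

PROFILE_NAMES = ("LOW30", "MED50", "HIGH163", "NICKTOP", "NICKBOT", "SSB",
                 "CANONICAL")

_DEFAULT_KON = 5.9e5  # M^-1 s^-1
_REHYB_RATE = 2000.0  # bp/s ("rapid" rehybridization)
_NICK_POSITION = 500.0  # bp downstream of the loading site
_NICK_JITTER = 100.0  # bp


def _base_profile(spec_name: str, name: str) -> ExperimentProfile:
    s = _PROFILE_SPECS[spec_name]
    tau_unwind = s["L"] / s["v"]
    tau_rehyb = s["L"] / _REHYB_RATE
    kin = MotorKinetics(
        unwind_rate_mean=s["v"],
        unwind_rate_cv=s["cv"],
        detach_per_bp=1.0 / s["L"],
        pause_entry_rate=entry_rate_from_fraction(s["pause_u"], tau_unwind),
        rehyb_pause_entry_rate=entry_rate_from_fraction(s["pause_r"],
                                                        tau_rehyb),
        backslide_rate=entry_rate_from_fraction(s["backslide"], tau_unwind),
        backslide_complete_fraction=s["complete"],
        rehyb_rate=_REHYB_RATE,
    )
    if s["dwell"] is not None:
        kon = 1.0 / (s["dwell"] * s["conc"])
    else:
        kon = _DEFAULT_KON
    init = InitiationModel(kon=kon, protein_conc=s["conc"])
    return ExperimentProfile(name=name, tether=TetherDesign(), kinetics=kin,
                             initiation=init, noise=NoiseModel(), force=8.0)


def build_profile(name: str) -> ExperimentProfile:
    """Return the frozen built-in parameter bundle for a named condition.

    Valid names: LOW30, MED50, HIGH163 (protein concentration series),
    NICKTOP / NICKBOT (nicked tethers at 30 nM), SSB (SSB co-incubation at
    30 nM), CANONICAL (a non-looping comparison motor at 30 nM kinetics).
    """
    if name not in PROFILE_NAMES:
        raise ValueError(f"unknown profile {name!r}; valid names: "
                         f"{', '.join(PROFILE_NAMES)}")
    if name in _PROFILE_SPECS:
        return _base_profile(name, name)
    base = _base_profile("LOW30", name)
    if name == "NICKTOP":
        tether = replace(base.tether,
                         nick=Nick("top", _NICK_POSITION, _NICK_JITTER))
        return replace(base, tether=tether)
    if name == "NICKBOT":
        # printed processivity on the bottom-nicked tether: 870 bp, nick
        # transparent to translocation
        tau = 870.0 / base.kinetics.unwind_rate_mean
        kin = replace(base.kinetics, detach_per_bp=1.0 / 870.0,
                      pause_entry_rate=entry_rate_from_fraction(0.05, tau),
                      backslide_rate=entry_rate_from_fraction(0.24, tau))
        tether = replace(base.tether,
                         nick=Nick("bottom", _NICK_POSITION, _NICK_JITTER))
        return replace(base, tether=tether, kinetics=kin)
    if name == "SSB":
        return replace(base, ssb_mode=SsbMode())
    if name == "CANONICAL":
        return replace(base, geometry="canonical")
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Event-level simulation


def _draw_event_rate(k: MotorKinetics, rng: np.random.Generator) -> float:
    """Per-event unwinding rate: Gaussian between events, constant within."""
    sd = k.unwind_rate_cv * k.unwind_rate_mean
    if sd == 0:
        return k.unwind_rate_mean
    for _ in range(1000):
        v = rng.normal(k.unwind_rate_mean, sd)
        if v > k.rate_floor:
            return float(v)
    raise RuntimeError("could not draw a positive unwinding rate")


def _pause_duration(k: MotorKinetics, rng: np.random.Generator) -> float:
    scale = k.pause_mean_duration - k.pause_min_duration
    return k.pause_min_duration + (rng.exponential(scale) if scale > 0 else 0.0)


def simulate_event_lengths(k: MotorKinetics, n: int, seed=None,
                           tether: TetherDesign | None = None) -> np.ndarray:
    """Draw n event lengths (bp) from the state machine's event-length law.

    Exponential with mean 1/detach_per_bp; on a top-strand-nicked tether the
    lengths are truncated at the (jittered) arrest position.  Lengths are
    clipped at the track length.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    lengths = rng.exponential(k.mean_event_length, size=int(n))
    track = tether.track_length if tether is not None else None
    if tether is not None and tether.nick is not None \
            and tether.nick.strand == "top":
        jit = np.clip(rng.normal(0.0, tether.nick.jitter_sd, size=int(n)),
                      -3.0 * tether.nick.jitter_sd,
                      3.0 * tether.nick.jitter_sd)
        arrest = np.clip(tether.nick.position + jit, 1.0, track)
        lengths = np.minimum(lengths, arrest)
    if track is not None:
        n_clip = int(np.sum(lengths > track))
        if n_clip:
            logger.warning("%d event length(s) clipped at the %g bp track",
                           n_clip, track)
        lengths = np.minimum(lengths, track)
    return lengths


def _simulate_one_event(profile: ExperimentProfile, t0: float,
                        rng: np.random.Generator,
                        points: list, truth: list) -> float:
    """Append one unwinding + rehybridization cycle starting at time t0.

    Returns the time at which the tether is fully rehybridised.
    """
    k = profile.kinetics
    tether = profile.tether
    ssb = profile.ssb_mode
    rehyb_speed = k.rehyb_rate / (ssb.rehyb_slowdown if ssb else 1.0)
    backslide_rate = k.backslide_rate * (ssb.backslide_suppression if ssb
                                         else 1.0)

    v_e = _draw_event_rate(k, rng)
    length = float(rng.exponential(k.mean_event_length))
    if length > tether.track_length:
        logger.warning("event length %.0f bp clipped at the %.0f bp track",
                       length, tether.track_length)
        length = tether.track_length
    arrested = False
    target = length
    if tether.nick is not None and tether.nick.strand == "top":
        # jitter hard-bounded at 3 SD: the motor never passes the lesion
        jit = float(np.clip(rng.normal(0.0, tether.nick.jitter_sd),
                            -3.0 * tether.nick.jitter_sd,
                            3.0 * tether.nick.jitter_sd))
        arrest_at = float(np.clip(tether.nick.position + jit, 1.0,
                                  tether.track_length))
        if arrest_at <= length:
            target = arrest_at
            arrested = True

    # per-bp hazards: entries are Poisson along the distance translocated
    pause_per_bp = k.pause_entry_rate / k.unwind_rate_mean
    backslide_per_bp = backslide_rate / k.unwind_rate_mean

    truth.append(GroundTruthEvent("initiation", t0, t0, 0.0, 0.0))
    t = t0
    pos = 0.0
    t_u_start = t
    while pos < target - 1e-9:
        d_done = target - pos
        d_pause = rng.exponential(1.0 / pause_per_bp) \
            if pause_per_bp > 0 else math.inf
        d_bs = rng.exponential(1.0 / backslide_per_bp) \
            if backslide_per_bp > 0 else math.inf
        d = min(d_done, d_pause, d_bs)
        pos += d
        t += d / v_e
        points.append((t, pos))
        if d == d_done:
            break
        if d == d_pause:
            d = _pause_duration(k, rng)
            truth.append(GroundTruthEvent("pause", t, t + d, pos, pos,
                                          phase="unwinding"))
            t += d
            points.append((t, pos))
        else:  # backslide
            complete = bool(rng.random() < k.backslide_complete_fraction)
            new_pos = 0.0 if complete else pos * float(rng.uniform(0.1, 0.9))
            retreat_t = (pos - new_pos) / rehyb_speed
            truth.append(GroundTruthEvent("backslide", t, t + retreat_t
                                          + k.backslide_restart_delay,
                                          pos, new_pos, complete=complete))
            t += retreat_t
            points.append((t, new_pos))
            t += k.backslide_restart_delay
            points.append((t, new_pos))
            pos = new_pos
    truth.append(GroundTruthEvent("unwinding", t_u_start, t, 0.0, target,
                                  rate=v_e))

    if arrested:
        stall = rng.exponential(k.arrest_stall_mean) \
            if k.arrest_stall_mean > 0 else 0.0
        t += stall
        points.append((t, pos))

    # terminal rehybridization back to baseline, possibly with pauses
    t_r_start = t
    r_start_pos = pos
    while pos > 1e-9:
        dt_done = pos / rehyb_speed
        dt_pause = rng.exponential(1.0 / k.rehyb_pause_entry_rate) \
            if k.rehyb_pause_entry_rate > 0 else math.inf
        dt = min(dt_done, dt_pause)
        pos = max(pos - rehyb_speed * dt, 0.0)
        t += dt
        points.append((t, pos))
        if dt == dt_pause and pos > 1e-9:
            d = _pause_duration(k, rng)
            truth.append(GroundTruthEvent("pause", t, t + d, pos, pos,
                                          phase="rehybridization"))
            t += d
            points.append((t, pos))
    truth.append(GroundTruthEvent(
        "rehybridization", t_r_start, t, r_start_pos, 0.0,
        complete=not arrested))
    return t


def simulate_trace(profile: ExperimentProfile, duration: float,
                   seed: int | None = 0,
                   include_lateral: bool = False,
                   initiation_rate_override: float | None = None) -> Trace:
    """Simulate a bead-height trace of `duration` seconds.

    Identical (profile, duration, seed) give identical traces.  Setting
    ``initiation_rate_override=0`` produces a flat (no-event) trace; any
    other positive value replaces the profile's initiation rate (s^-1).
    """
    if not (math.isfinite(duration) and duration > 0):
        raise ValueError(f"duration must be > 0 s, got {duration!r}")
    rng = np.random.default_rng(seed)

    if initiation_rate_override is None:
        mean_wait = profile.initiation.mean_waiting
    elif initiation_rate_override < 0:
        raise ValueError("initiation rate override must be >= 0")
    elif initiation_rate_override == 0:
        mean_wait = math.inf
    else:
        mean_wait = 1.0 / initiation_rate_override

    points: list[tuple[float, float]] = [(0.0, 0.0)]
    truth: list[GroundTruthEvent] = []
    t = 0.0
    while True:
        wait = rng.exponential(mean_wait) if math.isfinite(mean_wait) \
            else math.inf
        t_init = t + wait
        if t_init >= duration:
            break
        points.append((t_init, 0.0))
        t = _simulate_one_event(profile, t_init, rng, points, truth)
        if t >= duration:
            break

    n = int(round(duration * profile.noise.sampling_rate))
    times = np.arange(n) / profile.noise.sampling_rate
    pts = np.asarray(points, float)
    # deduplicate non-increasing timestamps (zero-length exponential draws)
    keep = np.concatenate([[True], np.diff(pts[:, 0]) > 0])
    pts = pts[keep]
    pos_bp = np.interp(times, pts[:, 0], pts[:, 1])

    rise = duplex_rise_per_bp(profile.force, profile.duplex)
    baseline_z = profile.tether.insert_length * rise
    z_clean = baseline_z - pos_bp * profile.nm_per_bp
    noise = rng.normal(0.0, profile.noise.z_noise_sd, size=n) \
        if profile.noise.z_noise_sd > 0 else np.zeros(n)
    z = z_clean + noise + profile.noise.drift_rate * times

    lateral = None
    if include_lateral:
        var = lateral_variance_at_force(
            profile.force, baseline_z,
            ThermalContext(profile.duplex.temperature))
        lateral = rng.normal(0.0, math.sqrt(var), size=n)

    truth = [ev for ev in truth if ev.t_start < duration]
    return Trace(times=times, z=z, force=profile.force,
                 profile_name=profile.name,
                 sampling_rate=profile.noise.sampling_rate,
                 seed=seed if isinstance(seed, int) else None,
                 truth=truth, lateral=lateral, baseline_z=baseline_z)
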