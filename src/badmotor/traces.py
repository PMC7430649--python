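"""Trace processing: 3 Hz filtering, worm-like-chain base-pair conversion,
velocity-threshold event segmentation, pause/backslide classification and
dwell-time extraction.

The processing chain mirrors standard magnetic-tweezers practice for motor
traces: the 60 Hz bead-height record is boxcar-averaged to 3 Hz, converted
from nm to bp through the WLC rise per base pair at the applied force, and
segmented on the central-difference velocity of the 3 Hz series.  Contiguous
runs of positive velocity above a threshold become unwinding events; fast
negative runs back to baseline are rehybridizations; near-zero-velocity
stretches inside an event are pauses; a retreat that does not reach baseline
(or that reaches it but is followed by renewed unwinding within a short
window) is attached to its parent event as a backslide.  Waiting times
between an event's return to baseline and the next initiation are recorded
as dwells.

Two detection thresholds act as left-truncations on the recovered
distributions - events shorter than ``min_event_length`` are discarded, and
re-initiations faster than ``backslide_window`` are absorbed into the
preceding event - so downstream exponential fits should be run with the
matching ``left_truncation`` argument of
:func:`badmotor.fits.fit_exponential_mean`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from badmotor.polymer import DuplexElasticity, SsDnaElasticity, \
    duplex_rise_per_bp, ssdna_extension_per_nt
from badmotor.simulate import Trace

logger = logging.getLogger(__name__)

__all__ = [
    "ProcessedTrace",
    "SegmentationConfig",
    "UnwindingEvent",
    "RehybEvent",
    "DwellRecord",
    "EventSummary",
    "downsample_filter",
    "z_to_bp",
    "segment_events",
    "summarize_events",
    "arrest_positions",
]


@dataclass
class ProcessedTrace:
    """A filtered trace, in nm (``units='nm'``) or baseline-referenced bp.

    ``values`` holds z in nm before conversion and motor position in bp
    (positive = forward translocation) after :func:`z_to_bp`.
    """

    times: np.ndarray
    values: np.ndarray
    units: str  # "nm" | "bp"
    rate: float  # Hz
    force: float  # pN
    window: int = 1  # boxcar window length in raw samples
    method: str = "boxcar"
    baseline_z: Optional[float] = None
    profile_name: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.units not in ("nm", "bp"):
            raise ValueError("units must be 'nm' or 'bp'")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    @property
    def position(self) -> np.ndarray:
        if self.units != "bp":
            raise ValueError("trace not yet converted to bp")
        return self.values


@dataclass
class SegmentationConfig:
    """Velocity-threshold segmentation parameters.

    At 3 Hz with ~10 bp of filtered noise the defaults bound false events
    below one per hour on flat traces while catching >90% of genuine events
    at the simulated study conditions.
    """

    v_min: float = 30.0  # bp/s minimum unwinding velocity
    v_pause: float = 30.0  # bp/s |velocity| below which a frame is paused
    t_min: float = 1.0  # s minimum run duration
    t_pause: float = 1.0  # s minimum pause duration
    min_event_length: float = 100.0  # bp
    baseline_tol: float = 50.0  # bp
    backslide_window: float = 1.5  # s
    backslide_min_depth: float = 50.0  # bp
    pause_smooth_frames: int = 3  # extra velocity smoothing for pause calls
    v_rehyb_pause: float = 75.0  # bp/s |velocity| for rehyb plateau calls
    dwell_split_min_length: float = 50.0  # bp net climb marking an initiation
    init_spike_height: float = 40.0  # bp single-frame excursion marking an
    # initiation too brief to form a velocity run (~4 sigma of 3 Hz noise)

    def __post_init__(self) -> None:
        if min(self.v_min, self.v_pause, self.t_min, self.t_pause,
               self.min_event_length, self.baseline_tol,
               self.backslide_window, self.backslide_min_depth,
               self.v_rehyb_pause, self.dwell_split_min_length) < 0:
            raise ValueError("segmentation thresholds must be >= 0")


@dataclass
class Pause:
    t_start: float
    t_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class Backslide:
    t_start: float
    t_end: float
    depth: float  # bp
    complete: bool


@dataclass
class UnwindingEvent:
    """One segmented unwinding event."""

    t_start: float
    t_end: float
    length: float  # bp, maximal baseline-referenced excursion
    mean_rate: float  # bp/s, pause-excluded
    mean_rate_incl_pauses: float  # bp/s, net length over total duration
    max_position: float  # bp
    pauses: list[Pause] = field(default_factory=list)
    backslides: list[Backslide] = field(default_factory=list)
    terminated_by: str = "rehybridization"  # | "arrest" | "trace-end"
    rehyb_end: Optional[float] = None  # time the tether re-reached baseline
    trace_id: int = 0


@dataclass
class RehybEvent:
    t_start: float
    t_end: float
    duration: float
    pauses: list[Pause] = field(default_factory=list)
    trace_id: int = 0


@dataclass
class DwellRecord:
    """Waiting time between an event's return to baseline and the next
    initiation on the same tether."""

    dt: float
    follows_backslide: bool = False
    trace_id: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dwell time must be > 0")


@dataclass
class EventSummary:
    """Per-condition tabulation of pause and backslide frequencies."""

    n_beads: int
    n_events: int
    pct_pause_unwinding: float
    pct_pause_rehyb: float
    pct_backslide: float
    pct_backslide_complete: float

    def __post_init__(self) -> None:
        for name in ("pct_pause_unwinding", "pct_pause_rehyb",
                     "pct_backslide", "pct_backslide_complete"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percentage in [0, 100]")


# ---------------------------------------------------------------------------


def downsample_filter(raw: Trace, target_rate: float = 3.0) -> ProcessedTrace:
    """Boxcar-average a raw trace down to `target_rate` (Hz).

    Non-overlapping windows of ``raw_rate/target_rate`` samples are averaged;
    a final partial window is truncated (with a log note).
    """
    if target_rate >= raw.sampling_rate:
        raise ValueError(
            f"target_rate {target_rate} Hz must be below the raw "
            f"{raw.sampling_rate} Hz")
    ratio = raw.sampling_rate / target_rate
    window = int(round(ratio))
    if abs(ratio - window) > 1e-9:
        logger.info("non-integer decimation %.3f rounded to %d samples",
                    ratio, window)
    n = raw.z.size // window
    if n * window != raw.z.size:
        logger.info("truncating %d trailing raw sample(s) in a partial window",
                    raw.z.size - n * window)
    z = raw.z[:n * window].reshape(n, window).mean(axis=1)
    t = raw.times[:n * window].reshape(n, window).mean(axis=1)
    return ProcessedTrace(times=t, values=z, units="nm",
                          rate=raw.sampling_rate / window, force=raw.force,
                          window=window, method="boxcar",
                          profile_name=raw.profile_name)


def _estimate_baseline(z: np.ndarray, bin_width_nm: float) -> float:
    """Mode of the height series (histogram) - robust to traces that start
    mid-event, unlike taking the first sample."""
    if z.size == 0:
        return 0.0
    lo, hi = float(z.min()), float(z.max())
    if hi - lo < bin_width_nm:
        return float(np.mean(z))
    nbins = max(int(math.ceil((hi - lo) / bin_width_nm)), 1)
    counts, edges = np.histogram(z, bins=nbins)
    i = int(np.argmax(counts))
    in_bin = (z >= edges[i]) & (z <= edges[i + 1])
    return float(z[in_bin].mean())


def z_to_bp(p: ProcessedTrace, force: float | None = None,
            e: DuplexElasticity | None = None,
            geometry: str = "looping",
            ssdna: SsDnaElasticity | None = None,
            baseline_z: float | None = None) -> ProcessedTrace:
    """Convert a nm trace to baseline-referenced bp of forward translocation.

    In the looping geometry the bead drops by the WLC rise per bp for every
    base pair translocated, so ``bp = (baseline_z - z) / rise(F)``.  In the
    canonical geometry the conversion constant is the signed ssDNA-minus-
    dsDNA extension difference per residue (positive above ~6 pN, negative
    below).  The baseline is estimated as the mode of the height histogram
    (25 bp bins) unless given.
    """
    if p.units != "nm":
        raise ValueError("expected a trace in nm")
    if force is None:
        force = p.force
    if force <= 0:
        raise ValueError(f"force must be > 0 pN, got {force!r}")
    if geometry not in ("looping", "canonical"):
        raise ValueError("geometry must be 'looping' or 'canonical'")
    e = e or DuplexElasticity()
    rise = duplex_rise_per_bp(force, e)
    if geometry == "looping":
        nm_per_bp = rise
    else:
        nm_per_bp = -(ssdna_extension_per_nt(force, ssdna or SsDnaElasticity())
                      - rise)
        if abs(nm_per_bp) < 1e-6:
            raise ValueError(
                "canonical geometry is degenerate at the ss/ds crossover "
                f"force ({force} pN): no height change per bp")
    if baseline_z is None:
        baseline_z = _estimate_baseline(p.values, 25.0 * abs(nm_per_bp))
    bp = (baseline_z - p.values) / nm_per_bp
    out = replace(p)
    out.values = bp
    out.units = "bp"
    out.baseline_z = float(baseline_z)
    return out


# ---------------------------------------------------------------------------
# segmentation


def _runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal [start, stop) index runs of True at least min_len long."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return [(a, b) for a, b in zip(starts, stops) if b - a >= min_len]


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def segment_events(p: ProcessedTrace,
                   cfg: SegmentationConfig | None = None,
                   trace_id: int = 0
                   ) -> tuple[list[UnwindingEvent], list[DwellRecord],
                              list[RehybEvent]]:
    """Segment a bp-converted trace into unwinding events, dwells and
    rehybridizations.

    Velocity is the central difference of the 3 Hz position series.  An
    additionally smoothed velocity (``pause_smooth_frames``) is used only
    for pause calls, where the raw central difference is too noisy at the
    pause threshold.  Empty traces and traces without events return empty
    lists rather than raising.
    """
    cfg = cfg or SegmentationConfig()
    if p.units != "bp":
        raise ValueError("segment_events expects a bp-converted trace")
    pos = p.values
    dt = 1.0 / p.rate
    if pos.size < 5 or pos.size * dt < 2 * cfg.t_min:
        # nothing segmentable in a trace shorter than two smoothing windows
        return [], [], []
    t = p.times
    v = np.gradient(pos, dt)
    v_smooth = _moving_average(v, cfg.pause_smooth_frames)

    n_min = max(int(round(cfg.t_min / dt)), 1)
    n_pause = max(int(round(cfg.t_pause / dt)), 2)
    up_runs = _runs(v > cfg.v_min, n_min)
    if not up_runs:
        return [], [], []

    # Merge runs whose separating gap is either short (a backslide retreat +
    # restart) or a plateau without substantial height loss (a pause).
    groups: list[list[tuple[int, int]]] = [[up_runs[0]]]
    for run in up_runs[1:]:
        prev = groups[-1][-1]
        gap_lo, gap_hi = prev[1], run[0]
        gap_t = (gap_hi - gap_lo) * dt
        # height lost in the gap: local maximum before the trough (the peak
        # frame itself is not part of the run - its central difference
        # already mixes in the retreat)
        gseg = pos[max(gap_lo - 1, 0):gap_hi + 1]
        i_tr = int(np.argmin(gseg))
        drop = float(gseg[:i_tr + 1].max() - gseg[i_tr])
        if gap_t <= cfg.backslide_window or drop <= cfg.backslide_min_depth:
            groups[-1].append(run)
        else:
            groups.append([run])

    events: list[UnwindingEvent] = []
    last_frame = pos.size - 1
    for g in groups:
        i0 = g[0][0]
        i1 = g[-1][1] - 1  # last moving frame
        start_idx = max(i0 - 1, 0)
        start_pos = pos[start_idx]
        seg = pos[start_idx:i1 + 2]
        max_pos = float(seg.max())
        t_start = float(t[start_idx])
        t_end = float(t[min(i1 + 1, last_frame)])
        duration = t_end - t_start

        # pause-excluded rate: average central-difference velocity over the
        # interior frames of each moving run (boundary frames are attenuated
        # by the boxcar filter and excluded when the run is long enough)
        vels = []
        for a, b in g:
            trim = 2 if b - a > 6 else (1 if b - a > 2 else 0)
            vels.append(v[a + trim:b - trim])
        vels = np.concatenate(vels)
        mean_rate = float(vels.mean()) if vels.size else float("nan")

        # first-order correction for boxcar peak clipping: the 3 Hz sample
        # containing the detachment averages climbing and rehybridizing
        # samples, shaving ~v*dt/2 off the apparent maximum
        length = max_pos - float(start_pos)
        if math.isfinite(mean_rate):
            length += mean_rate * dt / 2.0
        if length < cfg.min_event_length or duration < cfg.t_min:
            continue
        rate_incl = length / duration if duration > 0 else float("nan")

        # pauses: smoothed |v| below an adaptive threshold (half the event's
        # own median moving velocity, capped at v_pause so slow events are
        # not spuriously flagged) for >= t_pause, inside the moving span
        pauses: list[Pause] = []
        span = slice(i0, i1 + 1)
        v_moving = np.concatenate([v[a:b] for a, b in g])
        thr = min(cfg.v_pause, 0.5 * float(np.median(v_moving)))
        quiet = np.abs(v_smooth[span]) < thr
        for a, b in _runs(quiet, n_pause):
            a += i0
            b += i0
            drop = pos[max(a - 1, 0)] - pos[a:b].min()
            if drop > cfg.backslide_min_depth:
                continue
            pauses.append(Pause(float(t[a]), float(t[min(b, last_frame)])))

        # backslides: gaps between merged runs with substantial height loss
        backslides: list[Backslide] = []
        for (a0, a1), (b0, _) in zip(g[:-1], g[1:]):
            gap = pos[max(a1 - 1, 0):b0 + 1]
            i_tr = int(np.argmin(gap))
            trough = float(gap[i_tr])
            depth = float(gap[:i_tr + 1].max()) - trough
            if depth >= cfg.backslide_min_depth:
                backslides.append(Backslide(
                    float(t[a1 - 1]), float(t[b0]), depth,
                    complete=trough - start_pos <= cfg.baseline_tol))

        ev = UnwindingEvent(
            t_start=t_start, t_end=t_end, length=length,
            mean_rate=mean_rate, mean_rate_incl_pauses=rate_incl,
            max_position=max_pos, pauses=pauses, backslides=backslides,
            trace_id=trace_id)
        events.append(ev)

    # rehybridization after each event: from the last moving frame to the
    # first return within baseline_tol of the event's start level
    rehybs: list[RehybEvent] = []
    ends = [int(np.searchsorted(t, ev.t_end)) for ev in events]
    starts = [int(np.searchsorted(t, ev.t_start)) for ev in events]
    for j, ev in enumerate(events):
        i_end = ends[j]
        limit = starts[j + 1] if j + 1 < len(events) else pos.size
        seg = pos[i_end:limit]
        base_level = pos[max(starts[j] - 1, 0)]
        below = np.flatnonzero(seg <= base_level + cfg.baseline_tol)
        if below.size == 0:
            ev.terminated_by = "trace-end"
            continue
        i_base = i_end + int(below[0])
        ev.rehyb_end = float(t[i_base])
        # a plateau anywhere along the (otherwise fast) descent is a
        # rehybridization pause; the raw central difference with a generous
        # threshold discriminates plateaus (|v| ~ noise) from the descent
        # itself (hundreds to thousands of bp/s) with only 2 frames
        r_pauses: list[Pause] = []
        quiet = (np.abs(v[i_end:i_base + 1]) < cfg.v_rehyb_pause) & \
            (pos[i_end:i_base + 1] > base_level + cfg.baseline_tol) & \
            (pos[i_end:i_base + 1] < ev.max_position - cfg.backslide_min_depth)
        for a, b in _runs(quiet, max(n_pause - 1, 2)):
            r_pauses.append(Pause(float(t[i_end + a]),
                                  float(t[min(i_end + b, last_frame)])))
        rehybs.append(RehybEvent(t_start=ev.t_end, t_end=ev.rehyb_end,
                                 duration=ev.rehyb_end - ev.t_end,
                                 pauses=r_pauses, trace_id=trace_id))
        # terminal plateau at the maximum before descent marks an arrest
        i_desc = i_end
        while i_desc < i_base and pos[i_desc] > ev.max_position - \
                cfg.backslide_min_depth:
            i_desc += 1
        if (i_desc - i_end) * dt >= cfg.t_pause:
            ev.terminated_by = "arrest"
        if ev.t_end >= t[-1] - dt:
            ev.terminated_by = "trace-end"

    # dwells between an event's baseline return and the next initiation.
    # Initiations smaller than the minimum event length still terminate the
    # waiting time, so any up-run with a modest net climb
    # (dwell_split_min_length) acts as an initiation marker even when it is
    # not counted as an event; without this, sub-threshold events would be
    # absorbed into dwells and inflate the fitted mean.
    marker_times = []
    for a, b in up_runs:
        net = pos[a:b].max() - pos[max(a - 1, 0)]
        if net >= cfg.dwell_split_min_length:
            marker_times.append(float(t[max(a - 1, 0)]))
    # events too short/fast to sustain a velocity run still appear as brief
    # excursions above baseline; a rising edge from below half the spike
    # height marks them as initiations (the boxcar roughly halves a
    # sub-frame spike, so this catches excursions down to ~2x the height)
    if pos.size > 3 and cfg.init_spike_height > 0:
        high = pos > cfg.init_spike_height
        came_from_base = np.zeros_like(high)
        came_from_base[2:] = (np.minimum(pos[:-2], pos[1:-1])
                              < cfg.init_spike_height / 2.0)
        for i in np.flatnonzero(high & came_from_base):
            marker_times.append(float(t[i]) - dt)
    marker_times = np.sort(np.asarray(marker_times))

    dwells: list[DwellRecord] = []
    for prev, nxt in zip(events[:-1], events[1:]):
        if prev.rehyb_end is None:
            continue
        later = marker_times[(marker_times > prev.rehyb_end)
                             & (marker_times <= nxt.t_start + 1e-9)]
        end_t = float(later[0]) if later.size else nxt.t_start
        gap = end_t - prev.rehyb_end
        if gap <= 0:
            continue
        dwells.append(DwellRecord(
            dt=float(gap),
            follows_backslide=gap <= cfg.backslide_window,
            trace_id=trace_id))
    return events, dwells, rehybs


def censor_truncated(events: list[UnwindingEvent]) -> list[UnwindingEvent]:
    """Events cut off by the end of the recording are kept for counting but
    must not enter length/rate distributions; this filters them out."""
    return [ev for ev in events if ev.terminated_by != "trace-end"]


def summarize_events(events: list[UnwindingEvent],
                     rehybs: list[RehybEvent] | None = None) -> EventSummary:
    """Per-event pause/backslide percentages in the layout of the study's
    frequency table; empty input gives zero counts."""
    n = len(events)
    if n == 0:
        return EventSummary(0, 0, 0.0, 0.0, 0.0, 0.0)
    n_beads = len({ev.trace_id for ev in events})
    pct_pause_u = 100.0 * sum(1 for ev in events if ev.pauses) / n
    if rehybs is None:
        rehybs = []
    pct_pause_r = (100.0 * sum(1 for r in rehybs if r.pauses) / len(rehybs)
                   if rehybs else 0.0)
    with_bs = [ev for ev in events if ev.backslides]
    pct_bs = 100.0 * len(with_bs) / n
    all_bs = [b for ev in events for b in ev.backslides]
    pct_complete = (100.0 * sum(1 for b in all_bs if b.complete) / len(all_bs)
                    if all_bs else 0.0)
    return EventSummary(n_beads=n_beads, n_events=n,
                        pct_pause_unwinding=pct_pause_u,
                        pct_pause_rehyb=pct_pause_r,
                        pct_backslide=pct_bs,
                        pct_backslide_complete=pct_complete)


def arrest_positions(events: list[UnwindingEvent]) -> np.ndarray:
    """Maximum position reached per event (bp), for Gaussian-vs-exponential
    discrimination of arrest at a track lesion."""
    return np.asarray([ev.max_position for ev in events], float)
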