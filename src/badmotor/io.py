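"""Plain-text file formats, run configuration and provenance.

Traces are written as tab-separated text with '#'-prefixed header lines
carrying the profile name, force, sampling rate and seed; ground truth and
event/dwell tables are CSV.  Plain-text formats keep fixtures diffable.
Run configuration is YAML with schema validation (unknown keys rejected) so
that every random operation carries an explicit, recorded seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from badmotor.simulate import GroundTruthEvent, Trace
from badmotor.traces import (DwellRecord, EventSummary, RehybEvent,
                             SegmentationConfig, UnwindingEvent)

__all__ = [
    "write_trace", "read_trace", "write_truth", "read_truth",
    "events_to_frame", "dwells_to_frame", "rehybs_to_frame",
    "summary_to_frame", "format_summary_text",
    "RunConfig", "load_config", "config_hash",
]


def write_trace(trace: Trace, path) -> None:
    """Write a trace as TSV: '#' header lines, then time_s, z_nm columns
    (plus x_nm when lateral data are present)."""
    path = Path(path)
    cols = {"time_s": trace.times, "z_nm": trace.z}
    if trace.lateral is not None:
        cols["x_nm"] = trace.lateral
    header = [
        f"# profile: {trace.profile_name}",
        f"# force_pN: {trace.force:g}",
        f"# sampling_rate_Hz: {trace.sampling_rate:g}",
        f"# seed: {trace.seed if trace.seed is not None else ''}",
        f"# baseline_z_nm: {trace.baseline_z:.6f}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        fh.write("\t".join(cols) + "\n")
        data = np.column_stack(list(cols.values()))
        fmt = ["%.9f"] + ["%.3f"] * (len(cols) - 1)
        np.savetxt(fh, data, fmt=fmt, delimiter="\t")


def read_trace(path) -> Trace:
    """Read a TSV trace written by :func:`write_trace`.

    Malformed data rows are reported with their 1-based line numbers.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    colnames: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, val = line[1:].partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            if colnames is None:
                colnames = parts
                if "time_s" not in colnames or "z_nm" not in colnames:
                    raise ValueError(
                        f"{path}:{lineno}: expected a 'time_s\\tz_nm' "
                        f"column header, got {line!r}")
                continue
            try:
                rows.append([float(x) for x in parts])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: malformed data row {line!r}") from None
            if len(parts) != len(colnames):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(colnames)} columns, "
                    f"got {len(parts)}")
    if colnames is None:
        raise ValueError(f"{path}: no column header found")
    data = np.asarray(rows, float) if rows else \
        np.empty((0, len(colnames)))
    cols = {name: data[:, i] for i, name in enumerate(colnames)}
    seed = meta.get("seed", "")
    return Trace(
        times=cols["time_s"], z=cols["z_nm"],
        force=float(meta.get("force_pN", "nan")),
        profile_name=meta.get("profile", ""),
        sampling_rate=float(meta.get("sampling_rate_Hz", "60")),
        seed=int(seed) if seed else None,
        lateral=cols.get("x_nm"),
        baseline_z=float(meta.get("baseline_z_nm", "0")),
    )


def write_truth(truth: list[GroundTruthEvent], path) -> None:
    frame = pd.DataFrame(
        [dataclasses.asdict(ev) for ev in truth],
        columns=["type", "t_start", "t_end", "bp_start", "bp_end",
                 "complete", "phase", "rate"])
    frame.to_csv(path, index=False, float_format="%.3f")


def read_truth(path) -> list[GroundTruthEvent]:
    frame = pd.read_csv(path)
    out = []
    for row in frame.itertuples(index=False):
        complete = None if pd.isna(row.complete) else bool(row.complete)
        phase = None if pd.isna(row.phase) else str(row.phase)
        rate = None if pd.isna(row.rate) else float(row.rate)
        out.append(GroundTruthEvent(row.type, row.t_start, row.t_end,
                                    row.bp_start, row.bp_end, complete,
                                    phase, rate))
    return out


def events_to_frame(events: list[UnwindingEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append({
            "trace_id": ev.trace_id,
            "t_start_s": ev.t_start,
            "t_end_s": ev.t_end,
            "length_bp": ev.length,
            "mean_rate_bps": ev.mean_rate,
            "mean_rate_incl_pauses_bps": ev.mean_rate_incl_pauses,
            "max_position_bp": ev.max_position,
            "n_pauses": len(ev.pauses),
            "n_backslides": len(ev.backslides),
            "n_backslides_complete": sum(1 for b in ev.backslides
                                         if b.complete),
            "terminated_by": ev.terminated_by,
            "rehyb_end_s": ev.rehyb_end,
        })
    return pd.DataFrame(rows, columns=[
        "trace_id", "t_start_s", "t_end_s", "length_bp", "mean_rate_bps",
        "mean_rate_incl_pauses_bps", "max_position_bp", "n_pauses",
        "n_backslides", "n_backslides_complete", "terminated_by",
        "rehyb_end_s"])


def dwells_to_frame(dwells: list[DwellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"trace_id": d.trace_id, "dt_s": d.dt,
          "follows_backslide": d.follows_backslide} for d in dwells],
        columns=["trace_id", "dt_s", "follows_backslide"])


def rehybs_to_frame(rehybs: list[RehybEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"trace_id": r.trace_id, "t_start_s": r.t_start,
          "t_end_s": r.t_end, "duration_s": r.duration,
          "n_pauses": len(r.pauses)} for r in rehybs],
        columns=["trace_id", "t_start_s", "t_end_s", "duration_s",
                 "n_pauses"])


def summary_to_frame(summary: EventSummary) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(summary)])


def format_summary_text(summary: EventSummary, label: str = "") -> str:
    lines = [
        f"Condition: {label}" if label else "Condition summary",
        f"  beads analysed:                    {summary.n_beads}",
        f"  unwinding events:                  {summary.n_events}",
        f"  pauses during unwinding events:    {summary.pct_pause_unwinding:.0f}%",
        f"  pauses during rehybridization:     {summary.pct_pause_rehyb:.0f}%",
        f"  backsliding during unwinding:      {summary.pct_backslide:.0f}%"
        f" (of which {summary.pct_backslide_complete:.0f}% complete)",
    ]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# run configuration


_CONFIG_KEYS = {
    "profile": str,
    "seed": int,
    "duration_s": (int, float),
    "n_traces": int,
    "out_dir": str,
    "include_lateral": bool,
    "segmentation": dict,
}

_SEG_KEYS = {f.name for f in dataclasses.fields(SegmentationConfig)}


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration; every random operation receives an
    explicit seed recorded in the outputs."""

    profile: str = "LOW30"
    seed: int = 0
    duration_s: float = 3600.0
    n_traces: int = 1
    out_dir: str = "."
    include_lateral: bool = False
    segmentation: SegmentationConfig = dataclasses.field(
        default_factory=SegmentationConfig)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


def load_config(source) -> RunConfig:
    """Load a YAML config (path or mapping); unknown keys are rejected."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - set(_CONFIG_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; "
                         f"valid keys: {sorted(_CONFIG_KEYS)}")
    seg_raw = raw.pop("segmentation", {}) or {}
    unknown_seg = set(seg_raw) - _SEG_KEYS
    if unknown_seg:
        raise ValueError(f"unknown segmentation keys: {sorted(unknown_seg)}; "
                         f"valid keys: {sorted(_SEG_KEYS)}")
    for key, val in raw.items():
        expected = _CONFIG_KEYS[key]
        if not isinstance(val, expected):
            raise ValueError(f"config key {key!r} must be "
                             f"{expected}, got {type(val).__name__}")
    cfg = RunConfig(**raw, segmentation=SegmentationConfig(**seg_raw))
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of a config, embedded in reports for provenance."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
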