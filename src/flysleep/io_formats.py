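"""Readers, writers and canonical in-memory records for the pipeline's file formats.

Three kinds of raw input feed the pipeline:

* beam-cross activity monitor files (tab-separated, one row per minute,
  32 channels per monitor — the classic Trikinetics-style layout),
* stimulus logs from mechanical-arousal assays (headered CSV), and
* indirect-calorimetry tables of CO2 produced per 5-minute bin (headered CSV).

All times are held internally as 0-based minutes since recording start plus a
``zt0_offset_min`` anchor giving the first minute's position relative to
lights-on (ZT0).  Every interval is half-open: minute ``t`` covers
``[t, t+1)``.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ActivityTrace",
    "PositionTrace",
    "StimulusEvent",
    "MetabolicTrace",
    "ParseError",
    "read_dam_monitor",
    "write_dam_monitor",
    "read_stimulus_log",
    "write_stimulus_log",
    "read_vco2_table",
    "write_vco2_table",
    "read_position_trace",
]

N_CHANNELS = 32
N_META_FIELDS = 10  # reading index, date, time, status, six auxiliary fields
MINUTES_PER_DAY = 1440

PROTOCOLS = ("escalating", "fixed")


class ParseError(ValueError):
    """Raised when an input file violates its dialect; names the line at fault."""


def _parse_lights_on(lights_on: str) -> int:
    """Clock time 'HH:MM' -> minutes past midnight."""
    try:
        hh, mm = lights_on.split(":")
        minutes = int(hh) * 60 + int(mm)
    except ValueError as exc:
        raise ValueError(f"lights_on must be 'HH:MM', got {lights_on!r}") from exc
    if not 0 <= minutes < MINUTES_PER_DAY:
        raise ValueError(f"lights_on out of range: {lights_on!r}")
    return minutes


@dataclass
class ActivityTrace:
    """Per-fly, per-minute beam-cross counts anchored to Zeitgeber time.

    A minute is *active* iff its count is > 0 and *inactive* iff the count is
    0; every downstream scorer relies on exactly this dichotomy.
    """

    fly_id: str
    counts: np.ndarray
    zt0_offset_min: int = 0
    genotype: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size < 1:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.asarray(counts, dtype=np.int64)
            if not np.array_equal(rounded, counts):
                raise ValueError("counts must be integers")
            counts = rounded
        else:
            counts = counts.astype(np.int64, copy=False)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not 0 <= self.zt0_offset_min < MINUTES_PER_DAY:
            raise ValueError("zt0_offset_min must lie in [0, 1440)")
        self.counts = counts

    def __len__(self) -> int:
        return int(self.counts.size)

    @property
    def active(self) -> np.ndarray:
        """Boolean mask, True where the minute had at least one beam cross."""
        return self.counts > 0

    def zt_minute(self, index: int) -> int:
        """Absolute ZT-anchored minute of trace index ``index``."""
        return index + self.zt0_offset_min

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ActivityTrace):
            return NotImplemented
        return (
            self.fly_id == other.fly_id
            and self.zt0_offset_min == other.zt0_offset_min
            and self.genotype == other.genotype
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class PositionTrace:
    """Per-second planar positions from video tracking (after subsampling)."""

    fly_id: str
    xy_mm: np.ndarray
    fps: float = 1.0

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy_mm, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError("xy_mm must be an (n, 2) array")
        if not np.isfinite(xy).all():
            raise ValueError("coordinates must be finite")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        self.xy_mm = xy

    def movement_flags(self, movement_threshold_mm: float = 3.0) -> np.ndarray:
        """Frame-to-frame movement indicator: displacement > threshold."""
        d = np.linalg.norm(np.diff(self.xy_mm, axis=0), axis=1)
        return d > movement_threshold_mm


@dataclass(frozen=True)
class StimulusEvent:
    """A single mechanical stimulus delivered to one fly.

    ``intensity_g`` is platform acceleration in g; ``latency_s`` is the delay
    from delivery to first movement and is present iff the fly responded.
    """

    fly_id: str
    zt_min: int
    protocol: str
    intensity_g: float
    responded: bool
    latency_s: float | None = None

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.intensity_g < 0:
            raise ValueError("intensity_g must be >= 0")
        if self.responded and self.latency_s is None:
            raise ValueError("responded event requires a latency")
        if self.latency_s is not None and self.latency_s < 0:
            raise ValueError("latency_s must be >= 0")


@dataclass
class MetabolicTrace:
    """CO2 produced per fixed-width bin (arbitrary but consistent units)."""

    fly_id: str
    vco2: np.ndarray
    bin_min: int = 5
    zt0_offset_min: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.vco2, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("vco2 must be a non-empty 1-D sequence")
        if (v < 0).any() or not np.isfinite(v).all():
            raise ValueError("vco2 values must be finite and >= 0")
        if self.bin_min < 1 or MINUTES_PER_DAY % self.bin_min:
            raise ValueError("bin_min must divide 1440")
        if not 0 <= self.zt0_offset_min < MINUTES_PER_DAY:
            raise ValueError("zt0_offset_min must lie in [0, 1440)")
        self.vco2 = v

    def __len__(self) -> int:
        return int(self.vco2.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicTrace):
            return NotImplemented
        return (
            self.fly_id == other.fly_id
            and self.bin_min == other.bin_min
            and self.zt0_offset_min == other.zt0_offset_min
            and np.array_equal(self.vco2, other.vco2)
        )


# ---------------------------------------------------------------------------
# activity monitor files


def read_dam_monitor(
    path: str | Path,
    lights_on: str = "00:00",
    *,
    gap_fill: bool = False,
    channels: Sequence[int] | None = None,
    genotype: str = "",
) -> list[ActivityTrace]:
    """Read a 32-channel activity monitor file into per-fly traces.

    Each data line carries 10 metadata fields (reading index, ISO date,
    HH:MM:SS time, a status field and six auxiliary fields) followed by 32
    integer channel counts, all tab-separated; consecutive lines are 1-minute
    readings.  ``lights_on`` supplies the clock time of ZT0 so that
    ``zt0_offset_min`` can be anchored.

    By default only channels with at least one nonzero count are returned
    (an all-zero channel is indistinguishable from an unused one in this
    layout); pass ``channels`` (1-based) to force specific channels.
    Timestamp gaps are an error unless ``gap_fill`` inserts zero-count
    minutes.
    """
    path = Path(path)
    lights_on_min = _parse_lights_on(lights_on)
    rows: list[np.ndarray] = []
    times: list[_dt.datetime] = []
    with path.open("r", encoding="ascii") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != N_META_FIELDS + N_CHANNELS:
                raise ParseError(
                    f"{path.name}:{lineno}: expected "
                    f"{N_META_FIELDS + N_CHANNELS} tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                stamp = _dt.datetime.strptime(
                    f"{fields[1]} {fields[2]}", "%Y-%m-%d %H:%M:%S"
                )
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: bad timestamp") from exc
            try:
                counts = np.array(
                    [int(f) for f in fields[N_META_FIELDS:]], dtype=np.int64
                )
            except ValueError as exc:
                raise ParseError(
                    f"{path.name}:{lineno}: non-integer channel count"
                ) from exc
            if (counts < 0).any():
                raise ParseError(f"{path.name}:{lineno}: negative channel count")
            if times:
                delta = (stamp - times[-1]).total_seconds()
                if delta <= 0:
                    raise ParseError(
                        f"{path.name}:{lineno}: non-monotonic timestamp"
                    )
                if delta != 60:
                    if not gap_fill or delta % 60:
                        raise ParseError(
                            f"{path.name}:{lineno}: {delta:.0f}-s gap in "
                            "1-min readings (enable gap_fill to zero-fill)"
                        )
                    n_missing = int(delta // 60) - 1
                    for k in range(n_missing):
                        times.append(times[-1] + _dt.timedelta(minutes=1))
                        rows.append(np.zeros(N_CHANNELS, dtype=np.int64))
            times.append(stamp)
            rows.append(counts)
    if not rows:
        return []
    matrix = np.vstack(rows)  # minutes x channels
    first = times[0]
    zt0_offset = (first.hour * 60 + first.minute - lights_on_min) % MINUTES_PER_DAY
    if channels is None:
        keep = [ch for ch in range(N_CHANNELS) if matrix[:, ch].any()]
    else:
        keep = [ch - 1 for ch in channels]
        if any(ch < 0 or ch >= N_CHANNELS for ch in keep):
            raise ValueError("channels must be in 1..32")
    stem = path.stem
    return [
        ActivityTrace(
            fly_id=f"{stem}#ch{ch + 1:02d}",
            counts=matrix[:, ch],
            zt0_offset_min=zt0_offset,
            genotype=genotype,
        )
        for ch in keep
    ]


def write_dam_monitor(
    traces: Sequence[ActivityTrace],
    path: str | Path,
    lights_on: str = "00:00",
    start_date: str = "2024-01-01",
) -> None:
    """Write traces as a monitor file in the dialect ``read_dam_monitor`` accepts.

    Traces fill channels 1..n in order; unused channels are written as 0.
    All traces must share length and ``zt0_offset_min`` (they are rows of one
    instrument).  The first timestamp is placed at ``lights_on`` plus the
    common offset on ``start_date``.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("cannot write an empty monitor file (no time anchor)")
    if len(traces) > N_CHANNELS:
        raise ValueError(f"at most {N_CHANNELS} traces per monitor file")
    n = len(traces[0])
    offset = traces[0].zt0_offset_min
    for t in traces:
        if len(t) != n:
            raise ValueError("all traces must have equal length")
        if t.zt0_offset_min != offset:
            raise ValueError("all traces must share zt0_offset_min")
    lights_on_min = _parse_lights_on(lights_on)
    day = _dt.datetime.strptime(start_date, "%Y-%m-%d")
    start = day + _dt.timedelta(minutes=(lights_on_min + offset) % MINUTES_PER_DAY)
    matrix = np.zeros((n, N_CHANNELS), dtype=np.int64)
    for ch, t in enumerate(traces):
        matrix[:, ch] = t.counts
    path = Path(path)
    with path.open("w", encoding="ascii", newline="\n") as fh:
        for i in range(n):
            stamp = start + _dt.timedelta(minutes=i)
            meta = [
                str(i + 1),
                stamp.strftime("%Y-%m-%d"),
                stamp.strftime("%H:%M:%S"),
                "1",
            ] + ["0"] * 6
            fh.write("\t".join(meta + [str(c) for c in matrix[i]]) + "\n")


# ---------------------------------------------------------------------------
# stimulus logs

_STIM_HEADER = ["fly_id", "zt_min", "protocol", "intensity_g", "responded", "latency_s"]


def read_stimulus_log(path: str | Path) -> list[StimulusEvent]:
    """Read a stimulus log CSV, returning events sorted by (fly, time, intensity)."""
    path = Path(path)
    events: list[StimulusEvent] = []
    with path.open("r", encoding="ascii", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _STIM_HEADER:
            raise ParseError(f"{path.name}:1: expected header {','.join(_STIM_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_STIM_HEADER):
                raise ParseError(f"{path.name}:{lineno}: wrong field count")
            fly_id, zt_min, protocol, intensity, responded, latency = row
            if protocol not in PROTOCOLS:
                raise ParseError(
                    f"{path.name}:{lineno}: unknown protocol {protocol!r}"
                )
            if responded not in ("0", "1"):
                raise ParseError(f"{path.name}:{lineno}: responded must be 0 or 1")
            resp = responded == "1"
            if latency == "":
                if resp:
                    raise ParseError(
                        f"{path.name}:{lineno}: responded=1 requires a latency"
                    )
                lat = None
            else:
                lat = float(latency)
            try:
                events.append(
                    StimulusEvent(
                        fly_id=fly_id,
                        zt_min=int(zt_min),
                        protocol=protocol,
                        intensity_g=float(intensity),
                        responded=resp,
                        latency_s=lat,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
    events.sort(key=lambda e: (e.fly_id, e.zt_min, e.intensity_g))
    return events


def write_stimulus_log(events: Iterable[StimulusEvent], path: str | Path) -> None:
    events = sorted(events, key=lambda e: (e.fly_id, e.zt_min, e.intensity_g))
    with Path(path).open("w", encoding="ascii", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_STIM_HEADER)
        for e in events:
            writer.writerow(
                [
                    e.fly_id,
                    e.zt_min,
                    e.protocol,
                    _fmt(e.intensity_g),
                    int(e.responded),
                    "" if e.latency_s is None else _fmt(e.latency_s),
                ]
            )


def _fmt(x: float) -> str:
    """Repr-based float formatting: shortest string that round-trips."""
    return repr(float(x))


# ---------------------------------------------------------------------------
# VCO2 tables

_VCO2_HEADER = ["fly_id", "bin_index", "vco2"]


def read_vco2_table(
    path: str | Path, bin_min: int = 5, zt0_offset_min: int = 0
) -> list[MetabolicTrace]:
    """Read a per-bin CO2 table (CSV: fly_id,bin_index,vco2) into traces.

    Bin indices for each fly must be consecutive from 0; one trace is
    returned per fly, in first-appearance order.
    """
    path = Path(path)
    per_fly: dict[str, list[float]] = {}
    with path.open("r", encoding="ascii", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _VCO2_HEADER:
            raise ParseError(f"{path.name}:1: expected header {','.join(_VCO2_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ParseError(f"{path.name}:{lineno}: wrong field count")
            fly_id, idx_s, v_s = row
            try:
                idx, v = int(idx_s), float(v_s)
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: bad number") from exc
            if v < 0:
                raise ParseError(f"{path.name}:{lineno}: negative vco2")
            bins = per_fly.setdefault(fly_id, [])
            if idx != len(bins):
                raise ParseError(
                    f"{path.name}:{lineno}: bin index {idx} for {fly_id!r} "
                    f"(expected {len(bins)}: indices must be consecutive from 0)"
                )
            bins.append(v)
    return [
        MetabolicTrace(
            fly_id=fly_id,
            vco2=np.array(vals, dtype=float),
            bin_min=bin_min,
            zt0_offset_min=zt0_offset_min,
        )
        for fly_id, vals in per_fly.items()
    ]


def write_vco2_table(traces: Iterable[MetabolicTrace], path: str | Path) -> None:
    with Path(path).open("w", encoding="ascii", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_VCO2_HEADER)
        for t in traces:
            for k, v in enumerate(t.vco2):
                writer.writerow([t.fly_id, k, _fmt(v)])


def read_position_trace(path: str | Path, fps: float = 1.0) -> list[PositionTrace]:
    """Read per-frame positions (CSV: fly_id,x_mm,y_mm) into traces."""
    path = Path(path)
    per_fly: dict[str, list[tuple[float, float]]] = {}
    with path.open("r", encoding="ascii", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["fly_id", "x_mm", "y_mm"]:
            raise ParseError(f"{path.name}:1: expected header fly_id,x_mm,y_mm")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                per_fly.setdefault(row[0], []).append((float(row[1]), float(row[2])))
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path.name}:{lineno}: bad row") from exc
    return [
        PositionTrace(fly_id=f, xy_mm=np.array(xy, dtype=float), fps=fps)
        for f, xy in per_fly.items()
    ]
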