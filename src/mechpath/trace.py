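"""Domain types and file I/O for force-spectroscopy trajectories.

A :class:`Trace` is a uniformly sampled time series of extension (nm) and
force (pN) recorded under one of the AFM protocols:

* ``clamp``     - constant-force pulse (setpoint in pN),
* ``ramp``      - force increased linearly in time (ramp_rate in pN/s),
* ``extension`` - constant-velocity retraction (pull_speed in nm/s),
* ``cycles``    - alternating force pulses and zero-force quenches.

Traces are stored as plain-text TSV with a ``#``-prefixed ``key = value``
header block, columns ``time`` (s), ``extension`` (nm), ``force`` (pN), or as
an HDF5 container for batches (one group per trace; datasets time/extension/
force; attributes = header keys).  Numeric precision on disk: extension to
0.001 nm, force to 0.01 pN, time to 1 ns.

Detected unfolding steps are carried as :class:`StepEvent` rows collected in
an :class:`EventTable` together with per-trace summaries (number of steps,
number of intermediates = steps - 1, total length, first-passage time).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "PROTOCOLS",
    "Trace",
    "StepEvent",
    "EventTable",
    "TraceFormatError",
    "read_trace",
    "write_trace",
    "read_batch",
    "write_batch",
    "split_cycles",
]

PROTOCOLS = ("clamp", "ramp", "extension", "cycles")

#: Default instrument validity range for the sampling rate, Hz.
SAMPLING_RATE_RANGE = (500.0, 4000.0)

_FORMAT_MAGIC = "mechpath-trace v1"


class TraceFormatError(ValueError):
    """Trace file or object violates the documented format/invariants."""


@dataclass
class Trace:
    """One sampled force-spectroscopy trajectory plus protocol metadata."""

    time: np.ndarray  # s, strictly increasing, spacing 1/sampling_rate
    extension: np.ndarray  # nm
    force: np.ndarray  # pN
    protocol: str
    sampling_rate: float  # Hz
    trace_id: str = "trace"
    setpoint: float | None = None  # pN, clamp protocol
    ramp_rate: float | None = None  # pN/s, ramp protocol
    pull_speed: float | None = None  # nm/s, extension protocol
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.time.size else 0.0

    def validate(self, rate_range: tuple[float, float] = SAMPLING_RATE_RANGE) -> "Trace":
        """Check all invariants; raise :class:`TraceFormatError` on violation."""
        if self.protocol not in PROTOCOLS:
            raise TraceFormatError(f"unknown protocol: {self.protocol!r}")
        n = self.time.size
        if n == 0:
            raise TraceFormatError("trace has no samples")
        if self.extension.size != n or self.force.size != n:
            raise TraceFormatError(
                f"array length mismatch: time={n}, extension={self.extension.size}, "
                f"force={self.force.size}"
            )
        if not np.isfinite(self.sampling_rate) or self.sampling_rate <= 0:
            raise TraceFormatError(f"invalid sampling_rate: {self.sampling_rate}")
        lo, hi = rate_range
        if not (lo <= self.sampling_rate <= hi):
            raise TraceFormatError(
                f"sampling_rate {self.sampling_rate} Hz outside validity range "
                f"[{lo}, {hi}] Hz"
            )
        if n > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise TraceFormatError("time is not strictly increasing")
            expected = 1.0 / self.sampling_rate
            if np.max(np.abs(dt - expected)) > max(1e-9, 0.01 * expected):
                raise TraceFormatError(
                    "time spacing inconsistent with sampling_rate "
                    f"(expected {expected:.6g} s)"
                )
        if not (np.all(np.isfinite(self.extension)) and np.all(np.isfinite(self.force))):
            raise TraceFormatError("non-finite values in extension or force")
        if self.protocol == "clamp" and self.setpoint is None:
            raise TraceFormatError("clamp trace missing setpoint")
        if self.protocol == "ramp" and self.ramp_rate is None:
            raise TraceFormatError("ramp trace missing ramp_rate")
        if self.protocol == "extension" and self.pull_speed is None:
            raise TraceFormatError("extension trace missing pull_speed")
        return self

    def header(self) -> dict:
        """Metadata as a flat key -> value mapping (the TSV/HDF5 header block)."""
        h: dict = {
            "trace_id": self.trace_id,
            "protocol": self.protocol,
            "sampling_rate": self.sampling_rate,
        }
        if self.setpoint is not None:
            h["setpoint"] = self.setpoint
        if self.ramp_rate is not None:
            h["ramp_rate"] = self.ramp_rate
        if self.pull_speed is not None:
            h["pull_speed"] = self.pull_speed
        if self.seed is not None:
            h["seed"] = self.seed
        h.update(self.meta)
        return h


def _trace_from_header(header: dict, time, extension, force) -> Trace:
    header = dict(header)
    try:
        protocol = str(header.pop("protocol"))
    except KeyError:
        raise TraceFormatError("missing header field: protocol") from None
    try:
        sampling_rate = float(header.pop("sampling_rate"))
    except KeyError:
        raise TraceFormatError("missing header field: sampling_rate") from None
    kwargs: dict = {}
    for key, conv in (
        ("setpoint", float),
        ("ramp_rate", float),
        ("pull_speed", float),
        ("seed", int),
    ):
        if key in header:
            kwargs[key] = conv(header.pop(key))
    trace_id = str(header.pop("trace_id", "trace"))
    # remaining keys are free-form metadata; parse booleans written by us
    meta = {}
    for k, v in header.items():
        if isinstance(v, str) and v.lower() in ("true", "false"):
            meta[k] = v.lower() == "true"
        else:
            meta[k] = v
    return Trace(
        time=np.asarray(time, dtype=float),
        extension=np.asarray(extension, dtype=float),
        force=np.asarray(force, dtype=float),
        protocol=protocol,
        sampling_rate=sampling_rate,
        trace_id=trace_id,
        meta=meta,
        **kwargs,
    )


def write_trace(trace: Trace, path) -> None:
    """Write a validated trace to the TSV dialect (see module docstring)."""
    trace.validate()
    path = Path(path)
    lines = [f"# {_FORMAT_MAGIC}"]
    for key, value in trace.header().items():
        if isinstance(value, bool):
            value = "true" if value else "false"
        lines.append(f"# {key} = {value}")
    lines.append("time\textension\tforce")
    body = "\n".join(
        f"{t:.9f}\t{x:.3f}\t{f:.2f}"
        for t, x, f in zip(trace.time, trace.extension, trace.force)
    )
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def read_trace(path, rate_range: tuple[float, float] = SAMPLING_RATE_RANGE) -> Trace:
    """Read and validate a trace written by :func:`write_trace`."""
    path = Path(path)
    header: dict = {}
    columns: list[str] | None = None
    data_rows: list[str] = []
    with path.open() as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    header[key.strip()] = value.strip()
                continue
            if columns is None:
                columns = [c.strip() for c in line.split("\t")]
                continue
            data_rows.append(line)
    if columns is None:
        raise TraceFormatError(f"{path}: no column header line found")
    for required in ("time", "extension", "force"):
        if required not in columns:
            raise TraceFormatError(f"missing column: {required}")
    if not data_rows:
        raise TraceFormatError(f"{path}: no data rows")
    arr = np.loadtxt(data_rows, delimiter="\t", ndmin=2)
    if arr.shape[1] != len(columns):
        raise TraceFormatError(f"{path}: ragged data rows")
    cols = {name: arr[:, i] for i, name in enumerate(columns)}
    trace = _trace_from_header(header, cols["time"], cols["extension"], cols["force"])
    return trace.validate(rate_range)


def write_batch(traces: Iterable[Trace], path) -> None:
    """Write a batch of traces to one HDF5 file (group per trace)."""
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = _FORMAT_MAGIC
        for trace in traces:
            trace.validate()
            grp = fh.create_group(trace.trace_id)
            grp.create_dataset("time", data=trace.time)
            grp.create_dataset("extension", data=trace.extension)
            grp.create_dataset("force", data=trace.force)
            for key, value in trace.header().items():
                grp.attrs[key] = value


def read_batch(path, rate_range: tuple[float, float] = SAMPLING_RATE_RANGE) -> list[Trace]:
    """Read every trace from an HDF5 batch file, sorted by trace_id."""
    traces = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh.keys()):
            grp = fh[name]
            header = {k: v for k, v in grp.attrs.items()}
            header = {
                k: (v.item() if isinstance(v, np.generic) else v) for k, v in header.items()
            }
            trace = _trace_from_header(
                header, grp["time"][...], grp["extension"][...], grp["force"][...]
            )
            traces.append(trace.validate(rate_range))
    return traces


def split_cycles(trace: Trace, min_force: float = 1.0) -> list[Trace]:
    """Split a ``cycles`` trace into one clamp trace per force pulse.

    Pulse boundaries are the contiguous runs where the force exceeds
    ``min_force`` pN (the quench intervals sit at ~0 pN).  Each pulse is
    re-emitted as a clamp trace whose setpoint is the median in-pulse force
    and whose extension is re-zeroed to the pulse start.
    """
    if trace.protocol != "cycles":
        raise ValueError("split_cycles expects a cycles-protocol trace")
    active = trace.force > min_force
    edges = np.flatnonzero(np.diff(active.astype(int)))
    starts = list(np.flatnonzero(np.diff(np.concatenate(([0], active.astype(int)))) == 1))
    ends = list(np.flatnonzero(np.diff(np.concatenate((active.astype(int), [0]))) == -1) + 1)
    pulses = []
    for i, (a, b) in enumerate(zip(starts, ends)):
        if b - a < 2:
            continue
        sub = Trace(
            time=trace.time[a:b],
            extension=trace.extension[a:b] - trace.extension[a],
            force=trace.force[a:b],
            protocol="clamp",
            sampling_rate=trace.sampling_rate,
            trace_id=f"{trace.trace_id}/pulse{i}",
            setpoint=float(np.median(trace.force[a:b])),
            seed=trace.seed,
            meta=dict(trace.meta),
        )
        pulses.append(sub)
    return pulses


@dataclass(frozen=True)
class StepEvent:
    """One detected unfolding step within a trace."""

    trace_id: str
    step_index: int  # ordinal, 0-based
    step_length: float  # nm gained in this step
    cumulative_length: float  # nm gained since the first step
    dwell_before: float  # s spent in the preceding level
    force_at_step: float  # pN at the step time
    t_step: float  # s, absolute time of the step

    def __post_init__(self) -> None:
        if self.step_length <= 0:
            raise ValueError(f"step_length must be positive, got {self.step_length}")
        if self.dwell_before < 0:
            raise ValueError(f"dwell_before must be >= 0, got {self.dwell_before}")


_EVENT_COLUMNS = [
    "trace_id",
    "step_index",
    "step_length",
    "cumulative_length",
    "dwell_before",
    "force_at_step",
    "t_step",
]

_TRACE_COLUMNS = [
    "trace_id",
    "protocol",
    "force_condition",
    "n_steps",
    "n_intermediates",
    "total_length",
    "first_passage_time",
    "censored",
]


@dataclass
class EventTable:
    """Detected steps plus per-trace summaries for a batch of traces.

    ``events`` has one row per :class:`StepEvent`; ``traces`` one row per
    trace with columns n_steps, n_intermediates (= n_steps - 1, floored at
    0), total_length (cumulative length of the last step), first_passage_time
    (NaN when censored) and force_condition (setpoint pN for clamps,
    ramp rate pN/s for ramps).
    """

    events: pd.DataFrame
    traces: pd.DataFrame

    def __post_init__(self) -> None:
        self.events = self.events.reindex(columns=_EVENT_COLUMNS)
        self.traces = self.traces.reindex(
            columns=list(dict.fromkeys(_TRACE_COLUMNS + list(self.traces.columns)))
        )
        bad = self.traces[
            self.traces["n_intermediates"]
            != np.maximum(self.traces["n_steps"] - 1, 0)
        ]
        if len(bad):
            raise ValueError("n_intermediates must equal max(n_steps - 1, 0)")

    @classmethod
    def from_events(
        cls,
        events: Sequence[StepEvent],
        per_trace: pd.DataFrame,
    ) -> "EventTable":
        ev = pd.DataFrame([asdict(e) for e in events], columns=_EVENT_COLUMNS)
        return cls(events=ev, traces=per_trace.reset_index(drop=True))

    @property
    def step_lengths(self) -> np.ndarray:
        """Pooled step lengths (nm) across all traces - the clustering input."""
        return self.events["step_length"].to_numpy(dtype=float)

    def for_force(self, force_condition: float) -> "EventTable":
        """Subset to one force condition (events and summaries)."""
        tr = self.traces[np.isclose(self.traces["force_condition"], force_condition)]
        ev = self.events[self.events["trace_id"].isin(tr["trace_id"])]
        return EventTable(events=ev.reset_index(drop=True), traces=tr.reset_index(drop=True))

    def to_tsv(self, events_path, traces_path) -> None:
        self.events.to_csv(events_path, sep="\t", index=False, float_format="%.6g")
        self.traces.to_csv(traces_path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, events_path, traces_path) -> "EventTable":
        ev = pd.read_csv(events_path, sep="\t")
        tr = pd.read_csv(traces_path, sep="\t")
        return cls(events=ev, traces=tr)
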