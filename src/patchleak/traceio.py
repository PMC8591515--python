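"""Current-trace I/O and trace/protocol alignment.

Interchange format is a plain-text CSV dialect: header ``time,current``
(seconds, pA, outward positive), preceded by optional ``# key: value``
metadata comment lines (``id``, ``scenario``, ``seed``, free-form notes).
Currents are written with 6 significant digits — below instrument noise —
and times with full (9 significant digit) precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import AlignmentError, MalformedInputError
from .protocol import VoltageProtocol, VoltageStep

SCENARIOS = ("I", "II", "III", "linear", "custom")


@dataclass(frozen=True)
class TraceMeta:
    """Recording metadata carried in trace-file comment headers."""

    id: str = "trace"
    scenario: str = "custom"
    extras: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class CurrentTrace:
    """A sampled current recording (pA, outward positive) on a time base (s)."""

    times: np.ndarray
    currents: np.ndarray
    meta: TraceMeta = field(default_factory=TraceMeta)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.currents, dtype=float)
        if t.ndim != 1 or t.shape != c.shape:
            raise MalformedInputError("time and current must be 1-D and equal length")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "currents", c)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def with_currents(self, currents: np.ndarray) -> "CurrentTrace":
        return replace(self, currents=np.asarray(currents, dtype=float))


def load_trace(path) -> CurrentTrace:
    """Read a trace from the ``time,current`` CSV dialect.

    ``# key: value`` comments become metadata; malformed data rows raise
    :class:`MalformedInputError` with the offending line number.
    """
    meta: dict[str, str] = {}
    times: list[float] = []
    currents: list[float] = []
    header_seen = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if not header_seen:
                cols = [c.strip() for c in line.split(",")]
                if cols[:2] != ["time", "current"]:
                    raise MalformedInputError(
                        f"{path}:{lineno}: expected header 'time,current', got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) < 2:
                raise MalformedInputError(f"{path}:{lineno}: malformed row {line!r}")
            try:
                times.append(float(parts[0]))
                currents.append(float(parts[1]))
            except ValueError as exc:
                raise MalformedInputError(
                    f"{path}:{lineno}: non-numeric value in row {line!r}"
                ) from exc
    if not header_seen:
        raise MalformedInputError(f"{path}: missing 'time,current' header")
    if len(times) < 2:
        raise MalformedInputError(f"{path}: need at least 2 samples, got {len(times)}")
    extras = {k: v for k, v in meta.items() if k not in ("id", "scenario")}
    return CurrentTrace(
        times=np.array(times),
        currents=np.array(currents),
        meta=TraceMeta(
            id=meta.get("id", Path(path).stem),
            scenario=meta.get("scenario", "custom"),
            extras=extras,
        ),
    )


def save_trace(trace: CurrentTrace, path) -> None:
    """Write a trace in the CSV dialect (times %.9g, currents %.6g)."""
    if len(trace) == 0:
        raise MalformedInputError("refusing to write an empty trace")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# id: {trace.meta.id}\n")
        fh.write(f"# scenario: {trace.meta.scenario}\n")
        for key, val in trace.meta.extras.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("time,current\n")
        for t, c in zip(trace.times, trace.currents):
            fh.write(f"{t:.9g},{c:.6g}\n")


def save_cohort(traces: Iterable[CurrentTrace], directory) -> list[Path]:
    """Write each trace to ``<directory>/<id>.csv``; ids must be distinct."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    seen: set[str] = set()
    for trace in traces:
        if trace.meta.id in seen:
            raise MalformedInputError(f"duplicate trace id {trace.meta.id!r}")
        seen.add(trace.meta.id)
        p = directory / f"{trace.meta.id}.csv"
        save_trace(trace, p)
        paths.append(p)
    return paths


class AlignedTrace:
    """Read-only view of a trace indexed by a protocol's steps.

    Never copies or modifies the underlying samples; slicing is by index
    arithmetic on the shared uniform time base.
    """

    def __init__(self, trace: CurrentTrace, protocol: VoltageProtocol):
        self.trace = trace
        self.protocol = protocol

    def _slice(self, t_start: float, t_end: float) -> slice:
        dt = self.protocol.dt
        i0 = int(round((t_start - self.trace.times[0]) / dt))
        i1 = int(round((t_end - self.trace.times[0]) / dt))
        return slice(max(i0, 0), min(i1, len(self.trace)))

    def step_times(self, step: VoltageStep) -> np.ndarray:
        return self.trace.times[self._slice(step.t_start, step.t_end)]

    def step_currents(self, step: VoltageStep) -> np.ndarray:
        return self.trace.currents[self._slice(step.t_start, step.t_end)]

    def window_currents(self, t_start: float, t_end: float) -> np.ndarray:
        return self.trace.currents[self._slice(t_start, t_end)]


def align(
    trace: CurrentTrace,
    protocol: VoltageProtocol,
    rel_tol: float = 1e-6,
) -> AlignedTrace:
    """Align a trace to a protocol, validating time base compatibility.

    Sampling intervals must agree within ``rel_tol`` (relative); lengths
    within one sample (a one-sample mismatch warns, more raises).
    """
    dt_t, dt_p = trace.dt, protocol.dt
    if abs(dt_t - dt_p) > rel_tol * dt_p:
        raise AlignmentError(
            f"sampling interval mismatch: trace {dt_t:g} s vs protocol {dt_p:g} s"
        )
    n_t, n_p = len(trace), len(protocol.times)
    if abs(n_t - n_p) > 1:
        raise AlignmentError(f"length mismatch: trace {n_t} vs protocol {n_p} samples")
    if n_t != n_p:
        warnings.warn(
            f"trace has {n_t} samples, protocol {n_p}; aligning on the overlap",
            stacklevel=2,
        )
    return AlignedTrace(trace, protocol)
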