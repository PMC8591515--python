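"""Voltage-clamp command protocols: loading and step/ramp segmentation.

A protocol is a uniformly sampled command-voltage time series (seconds, mV).
It is decomposed into *steps* — maximal runs during which the command stays
within ±``delta_v`` of the run median for at least ``min_duration`` — and
*ramps*, everything else.  Steps carry an *occurrence* counter so that, e.g.,
"the first +40 mV step" of a staircase protocol is addressable even when the
same voltage is visited repeatedly.

All intervals are half-open ``[t_start, t_end)`` with time zero at the first
sample.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MalformedInputError, StepNotFoundError

#: default tolerance (mV) for "the voltage stays constant" and for matching
#: step voltages when counting occurrences
DEFAULT_DELTA_V = 0.5
#: default minimum duration (s) for a flat run to count as a step
DEFAULT_MIN_DURATION = 0.05


@dataclass(frozen=True)
class VoltageStep:
    """One constant-voltage segment of a protocol.

    Attributes
    ----------
    index : int
        Chronological 0-based position among the protocol's steps.
    t_start, t_end : float
        Half-open interval ``[t_start, t_end)`` in seconds.
    voltage : float
        Command voltage (mV): the median of the run's samples.
    occurrence : int
        1-based chronological rank among steps sharing this voltage
        (matched within the segmentation tolerance).
    """

    index: int
    t_start: float
    t_end: float
    voltage: float
    occurrence: int

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class VoltageProtocol:
    """A sampled command-voltage waveform with its step/ramp segmentation."""

    times: np.ndarray
    voltages: np.ndarray
    steps: tuple[VoltageStep, ...]
    ramps: tuple[tuple[float, float], ...]
    holding_voltage: float
    delta_v: float = DEFAULT_DELTA_V
    dt: float = field(init=False, default=0.0)

    def __post_init__(self):
        object.__setattr__(self, "dt", float(self.times[1] - self.times[0]))

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0] + self.dt)

    @property
    def step_voltages(self) -> np.ndarray:
        return np.array([s.voltage for s in self.steps])

    @classmethod
    def from_samples(
        cls,
        times: np.ndarray,
        voltages: np.ndarray,
        delta_v: float = DEFAULT_DELTA_V,
        min_duration: float = DEFAULT_MIN_DURATION,
    ) -> "VoltageProtocol":
        times = np.asarray(times, dtype=float)
        voltages = np.asarray(voltages, dtype=float)
        _validate_samples(times, voltages)
        steps, ramps = segment_steps(times, voltages, delta_v, min_duration)
        return cls(
            times=times,
            voltages=voltages,
            steps=tuple(steps),
            ramps=tuple(ramps),
            holding_voltage=float(voltages[0]),
            delta_v=delta_v,
        )

    def sample_slice(self, t_start: float, t_end: float) -> slice:
        """Index slice of samples falling in ``[t_start, t_end)``."""
        i0 = int(round((t_start - self.times[0]) / self.dt))
        i1 = int(round((t_end - self.times[0]) / self.dt))
        return slice(max(i0, 0), min(i1, len(self.times)))


def _validate_samples(times: np.ndarray, voltages: np.ndarray) -> None:
    if times.ndim != 1 or times.shape != voltages.shape:
        raise MalformedInputError("time and voltage must be 1-D arrays of equal length")
    if len(times) < 2:
        raise MalformedInputError(f"need at least 2 samples, got {len(times)}")
    dts = np.diff(times)
    if np.any(dts <= 0):
        bad = int(np.argmax(dts <= 0))
        raise MalformedInputError(
            f"time must be strictly increasing (violated at sample {bad + 1})"
        )
    dt = dts[0]
    if not np.allclose(dts, dt, rtol=1e-3, atol=1e-12):
        raise MalformedInputError("sampling interval is not uniform")
    if np.any(times < 0):
        raise MalformedInputError("time must be non-negative")


def load_protocol(
    path,
    time_unit: str = "s",
    delta_v: float = DEFAULT_DELTA_V,
    min_duration: float = DEFAULT_MIN_DURATION,
) -> VoltageProtocol:
    """Load a ``time,voltage`` CSV protocol and segment it.

    Parameters
    ----------
    path : path-like
        Two-column CSV, header ``time,voltage``, optional ``#`` comments.
    time_unit : {"s", "ms"}
        Unit of the file's time column; converted to seconds on load.
    """
    scale = {"s": 1.0, "ms": 1e-3}.get(time_unit)
    if scale is None:
        raise MalformedInputError(f"unknown time unit {time_unit!r}")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise MalformedInputError(f"cannot parse protocol CSV {path}: {exc}") from exc
    if list(df.columns[:2]) != ["time", "voltage"]:
        raise MalformedInputError(
            f"{path}: expected header 'time,voltage', got {list(df.columns)!r}"
        )
    if df[["time", "voltage"]].isna().any().any():
        row = int(df[["time", "voltage"]].isna().any(axis=1).idxmax())
        raise MalformedInputError(f"{path}: malformed row at data line {row + 1}")
    return VoltageProtocol.from_samples(
        df["time"].to_numpy() * scale,
        df["voltage"].to_numpy(),
        delta_v=delta_v,
        min_duration=min_duration,
    )


def save_protocol(protocol: VoltageProtocol, path) -> None:
    """Write a protocol back to the ``time,voltage`` CSV dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time,voltage\n")
        for t, v in zip(protocol.times, protocol.voltages):
            fh.write(f"{t:.9g},{v:.9g}\n")


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _median_sorted(vals: list) -> float:
    n = len(vals)
    mid = n // 2
    return vals[mid] if n % 2 else 0.5 * (vals[mid - 1] + vals[mid])


def _greedy_runs(v: np.ndarray, delta_v: float) -> list[tuple[int, int]]:
    """Maximal-to-the-right runs whose samples stay within ±delta_v of the
    run median, scanned left to right."""
    runs = []
    start = 0
    sorted_vals = [v[0]]
    for i in range(1, len(v)):
        bisect.insort(sorted_vals, v[i])
        m = _median_sorted(sorted_vals)
        if sorted_vals[-1] - m > delta_v or m - sorted_vals[0] > delta_v:
            runs.append((start, i))
            start = i
            sorted_vals = [v[i]]
    runs.append((start, len(v)))
    return runs


def _chunk_runs(v: np.ndarray, delta_v: float) -> list[tuple[int, int]]:
    """Split at large sample-to-sample jumps, then refine non-flat chunks.

    Flat chunks (ramp-free) are a single run; chunks containing gradual
    voltage change fall back to the greedy scan.  Equivalent to running the
    greedy scan on the whole record but much faster on step-dominated
    protocols.
    """
    jumps = np.flatnonzero(np.abs(np.diff(v)) > delta_v) + 1
    bounds = [0, *jumps.tolist(), len(v)]
    runs: list[tuple[int, int]] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        chunk = v[a:b]
        m = np.median(chunk)
        if chunk.max() - m <= delta_v and m - chunk.min() <= delta_v:
            runs.append((a, b))
        else:
            runs.extend((a + i, a + j) for i, j in _greedy_runs(chunk, delta_v))
    return runs


def segment_steps(
    times: np.ndarray,
    voltages: np.ndarray,
    delta_v: float = DEFAULT_DELTA_V,
    min_duration: float = DEFAULT_MIN_DURATION,
) -> tuple[list[VoltageStep], list[tuple[float, float]]]:
    """Decompose a sampled waveform into voltage steps and ramp intervals.

    Returns ``(steps, ramps)``.  Steps and ramps are disjoint half-open
    intervals that jointly cover ``[t[0], t[-1] + dt)``.  Occurrence counters
    are assigned chronologically per distinct voltage, voltages matched
    within ``delta_v``.
    """
    times = np.asarray(times, dtype=float)
    voltages = np.asarray(voltages, dtype=float)
    dt = times[1] - times[0]
    end_time = times[-1] + dt

    def t_of(idx: int) -> float:
        return end_time if idx >= len(times) else float(times[idx])

    runs = _chunk_runs(voltages, delta_v)
    steps: list[VoltageStep] = []
    ramps: list[tuple[float, float]] = []
    seen: list[tuple[float, int]] = []  # (reference voltage, count)
    ramp_open: float | None = None
    for a, b in runs:
        t0, t1 = t_of(a), t_of(b)
        if t1 - t0 >= min_duration:
            if ramp_open is not None:
                ramps.append((ramp_open, t0))
                ramp_open = None
            v_step = float(np.median(voltages[a:b]))
            occ = None
            for j, (ref, cnt) in enumerate(seen):
                if abs(v_step - ref) <= delta_v:
                    occ = cnt + 1
                    seen[j] = (ref, occ)
                    break
            if occ is None:
                occ = 1
                seen.append((v_step, 1))
            steps.append(
                VoltageStep(
                    index=len(steps),
                    t_start=t0,
                    t_end=t1,
                    voltage=v_step,
                    occurrence=occ,
                )
            )
        else:
            if ramp_open is None:
                ramp_open = t0
    if ramp_open is not None:
        ramps.append((ramp_open, end_time))
    return steps, ramps


def find_step(
    protocol: VoltageProtocol,
    voltage: float,
    occurrence: int = 1,
    delta_v: float | None = None,
) -> VoltageStep:
    """Return the ``occurrence``-th chronological step at ``voltage``.

    Voltage is matched within the protocol's segmentation tolerance (or
    ``delta_v`` if given).  Raises :class:`StepNotFoundError` on no match.
    """
    tol = protocol.delta_v if delta_v is None else delta_v
    for step in protocol.steps:
        if abs(step.voltage - voltage) <= tol and step.occurrence == occurrence:
            return step
    raise StepNotFoundError(voltage, occurrence)


def reconstruct_piecewise(
    protocol: VoltageProtocol, fill: float | None = None
) -> np.ndarray:
    """Piecewise-constant command reconstruction from the segmented steps.

    Samples inside ramps are left at the recorded command (or ``fill``).
    Mainly useful for checking that segmentation is idempotent.
    """
    v = np.full_like(protocol.voltages, np.nan if fill is None else fill)
    if fill is None:
        v[:] = protocol.voltages
    for step in protocol.steps:
        v[protocol.sample_slice(step.t_start, step.t_end)] = step.voltage
    return v
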