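"""Steady-state current-voltage relationships and cohort aggregation.

Per recording, the fitted steady state ``c`` of each step within the voltage
range (default [-120, +40] mV, endpoints inclusive) becomes one I-V point;
repeated visits to a voltage yield multiple points.  Curves are normalized
against the recording's own fitted linear leak line so that the leak line's
minimum over the range maps to 0 and its maximum to 1 — this puts recordings
with different seal resistances and reversal potentials on a common axis.

Cohorts are summarised per voltage by range and quartiles (five-number
summaries, linear-interpolation quartile method), the boxplot convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    AggregationError,
    DegenerateNormalizationError,
    EmptyCurveError,
)
from .kinetics import StepFit
from .leak import LinearLeak

DEFAULT_V_RANGE = (-120.0, 40.0)


@dataclass(frozen=True)
class IVPoint:
    voltage: float
    steady_state: float  # fitted c, pA
    step_index: int
    occurrence: int
    normalized: float | None = None


@dataclass(frozen=True)
class IVCurve:
    """Steady-state I-V points of one recording, raw or normalized."""

    recording_id: str
    points: tuple[IVPoint, ...]
    v_range: tuple[float, float] = DEFAULT_V_RANGE
    leak: LinearLeak | None = None
    n_excluded: int = 0

    @property
    def voltages(self) -> np.ndarray:
        return np.array([p.voltage for p in self.points])

    @property
    def is_normalized(self) -> bool:
        return bool(self.points) and all(p.normalized is not None for p in self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.recording_id,
                "voltage_mV": [p.voltage for p in self.points],
                "steady_state_pA": [p.steady_state for p in self.points],
                "normalized": [p.normalized for p in self.points],
                "step_index": [p.step_index for p in self.points],
                "occurrence": [p.occurrence for p in self.points],
            }
        )


@dataclass(frozen=True)
class CohortSummary:
    """Per-voltage five-number summaries of pooled normalized steady states."""

    table: pd.DataFrame  # voltage_mV, min, q1, median, q3, max, n_points
    n_recordings: int
    n_excluded: int

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def build_iv(
    fits: Sequence[StepFit],
    v_range: tuple[float, float] = DEFAULT_V_RANGE,
    recording_id: str = "trace",
) -> IVCurve:
    """Raw I-V curve from converged step fits within ``v_range`` (inclusive).

    Unconverged fits are excluded and counted; an empty result raises
    :class:`EmptyCurveError`.
    """
    lo, hi = min(v_range), max(v_range)
    points = []
    n_excluded = 0
    for f in fits:
        if f.step is None:
            n_excluded += 1
            continue
        if not (lo <= f.step.voltage <= hi):
            continue
        if not f.converged:
            n_excluded += 1
            continue
        points.append(
            IVPoint(
                voltage=f.step.voltage,
                steady_state=f.c,
                step_index=f.step.index,
                occurrence=f.step.occurrence,
            )
        )
    if not points:
        raise EmptyCurveError(
            f"no converged fits within [{lo:g}, {hi:g}] mV "
            f"({n_excluded} excluded)"
        )
    return IVCurve(
        recording_id=recording_id,
        points=tuple(points),
        v_range=(lo, hi),
        n_excluded=n_excluded,
    )


def leak_line_extrema(leak: LinearLeak, v_range: tuple[float, float]):
    """(L_min, L_max) of the leak line over the (inclusive) voltage range."""
    ends = leak.current(np.array(v_range, dtype=float))
    return float(ends.min()), float(ends.max())


def normalize_iv(curve: IVCurve, leak: LinearLeak) -> IVCurve:
    """Normalize so the leak line spans [0, 1] over the curve's v_range."""
    l_min, l_max = leak_line_extrema(leak, curve.v_range)
    span = l_max - l_min
    if span == 0.0:
        raise DegenerateNormalizationError(
            "leak line is flat over the voltage range (g_leak = 0); "
            "normalization undefined"
        )
    points = tuple(
        replace(p, normalized=(p.steady_state - l_min) / span) for p in curve.points
    )
    return replace(curve, points=points, leak=leak)


def normalized_leak_value(leak: LinearLeak, v: float, v_range) -> float:
    """Where the leak line itself sits on the normalized [0, 1] axis at v."""
    l_min, l_max = leak_line_extrema(leak, v_range)
    span = l_max - l_min
    if span == 0.0:
        raise DegenerateNormalizationError("flat leak line")
    return (float(leak.current(v)) - l_min) / span


def nonlinearity_profile(curve: IVCurve, leak: LinearLeak | None = None) -> pd.DataFrame:
    """Per-point deviation of the normalized steady state from the leak line.

    Positive deviation = superlinear (extra outward current); negative =
    sublinear (extra inward current).  Purely Ohmic recordings deviate only
    by noise.
    """
    leak = leak if leak is not None else curve.leak
    if leak is None or not curve.is_normalized:
        raise DegenerateNormalizationError("curve must be normalized first")
    rows = []
    for p in curve.points:
        rows.append(
            {
                "voltage_mV": p.voltage,
                "deviation": p.normalized
                - normalized_leak_value(leak, p.voltage, curve.v_range),
                "step_index": p.step_index,
                "occurrence": p.occurrence,
            }
        )
    return pd.DataFrame(rows)


def _voltage_key(v: float, delta_v: float) -> float:
    return round(v / (2 * delta_v)) * (2 * delta_v)


def aggregate_cohort(
    curves: Sequence[IVCurve],
    delta_v: float = 0.5,
) -> CohortSummary:
    """Pool normalized points per voltage across recordings and summarise.

    Every recording must cover the same set of step voltages (matched within
    ``delta_v``); repeated steps contribute separate points.  Quartiles use
    linear interpolation between order statistics.
    """
    if not curves:
        raise AggregationError("no curves to aggregate")
    for c in curves:
        if not c.is_normalized:
            raise DegenerateNormalizationError(
                f"curve {c.recording_id!r} is not normalized"
            )
    keysets = [
        frozenset(_voltage_key(p.voltage, delta_v) for p in c.points) for c in curves
    ]
    common = keysets[0]
    for c, ks in zip(curves[1:], keysets[1:]):
        if ks != common:
            missing = sorted(common ^ ks)
            raise AggregationError(
                f"curve {c.recording_id!r} has a mismatched voltage set; "
                f"differing voltages (mV): {missing}"
            )
    pooled: dict[float, list[float]] = {}
    for c in curves:
        for p in c.points:
            pooled.setdefault(_voltage_key(p.voltage, delta_v), []).append(p.normalized)
    rows = []
    for v in sorted(pooled):
        vals = np.array(pooled[v])
        q1, med, q3 = np.percentile(vals, [25, 50, 75], method="linear")
        rows.append(
            {
                "voltage_mV": v,
                "min": vals.min(),
                "q1": q1,
                "median": med,
                "q3": q3,
                "max": vals.max(),
                "n_points": len(vals),
            }
        )
    return CohortSummary(
        table=pd.DataFrame(rows),
        n_recordings=len(curves),
        n_excluded=sum(c.n_excluded for c in curves),
    )


def curve_from_frame(df: pd.DataFrame, v_range=DEFAULT_V_RANGE) -> IVCurve:
    """Rebuild an :class:`IVCurve` from its long-format table."""
    if df.empty:
        raise EmptyCurveError("empty I-V table")
    points = tuple(
        IVPoint(
            voltage=float(r.voltage_mV),
            steady_state=float(r.steady_state_pA),
            step_index=int(getattr(r, "step_index", -1)),
            occurrence=int(getattr(r, "occurrence", 1)),
            normalized=None if pd.isna(r.normalized) else float(r.normalized),
        )
        for r in df.itertuples()
    )
    rid = str(df["id"].iloc[0]) if "id" in df else "trace"
    return IVCurve(recording_id=rid, points=points, v_range=tuple(v_range))
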