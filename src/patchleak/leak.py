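"""Linear (Ohmic) leak estimation, evaluation and subtraction.

The classical leak model is

    I_leak = g_leak * (V_m - E_leak)

with g_leak the leak conductance and E_leak its reversal potential.  Units
are fixed at nS / mV / pA so the product needs no conversion factor.

The estimator is the two-step procedure used in practice: g_leak is the
ratio of the mean-current difference to the voltage difference between two
protocol steps (by default the -80 mV and -40 mV steps; for recordings whose
nonlinearity sits at negative voltages a high-voltage pair such as
(+40, +60) mV is used instead), the means taken over the last ``window``
seconds of each step; E_leak then follows algebraically from the first step
of the pair.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import DegeneratePairError
from .protocol import VoltageProtocol, find_step
from .traceio import AlignedTrace, CurrentTrace, align

DEFAULT_STEP_PAIR = (-80.0, -40.0)
DEFAULT_WINDOW = 0.5


@dataclass(frozen=True)
class LinearLeak:
    """Fitted Ohmic leak parameters with estimation provenance.

    ``g_leak`` in nS, ``E_leak`` in mV, so ``current(V)`` is in pA.
    """

    g_leak: float
    e_leak: float
    step_pair: tuple[float, float] = DEFAULT_STEP_PAIR
    occurrence: int = 1
    window: float = DEFAULT_WINDOW

    def __post_init__(self):
        if not np.isfinite(self.g_leak):
            raise ValueError("g_leak must be finite")
        if self.window <= 0:
            raise ValueError("window must be positive")

    def current(self, v_mv) -> np.ndarray:
        """Evaluate I_leak = g_leak * (V - E_leak) in pA."""
        return self.g_leak * (np.asarray(v_mv, dtype=float) - self.e_leak)

    def to_json(self) -> str:
        return json.dumps(
            {
                "g_leak_nS": self.g_leak,
                "E_leak_mV": self.e_leak,
                "step_pair_mV": list(self.step_pair),
                "occurrence": self.occurrence,
                "window_s": self.window,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearLeak":
        d = json.loads(text)
        return cls(
            g_leak=d["g_leak_nS"],
            e_leak=d["E_leak_mV"],
            step_pair=tuple(d["step_pair_mV"]),
            occurrence=d["occurrence"],
            window=d["window_s"],
        )


def leak_current(leak: LinearLeak, v_mv) -> np.ndarray:
    """Functional form of :meth:`LinearLeak.current`."""
    return leak.current(v_mv)


def _window_mean(
    aligned: AlignedTrace, step, window: float, blank: float
) -> float:
    """Mean current over the last ``window`` seconds of a step.

    Steps shorter than ``window + blank`` fall back to all samples after the
    blank, with a warning.
    """
    usable = step.duration - blank
    if usable <= 0:
        raise DegeneratePairError(
            f"step at {step.voltage:g} mV shorter than the {blank:g} s blank"
        )
    if window > usable:
        warnings.warn(
            f"step at {step.voltage:g} mV ({step.duration:g} s) is shorter than "
            f"window + blank ({window:g} + {blank:g} s); using all post-blank samples",
            stacklevel=3,
        )
        t0 = step.t_start + blank
    else:
        t0 = step.t_end - window
    return float(np.mean(aligned.window_currents(t0, step.t_end)))


def estimate_linear_leak(
    trace: CurrentTrace,
    protocol: VoltageProtocol,
    step_pair: tuple[float, float] = DEFAULT_STEP_PAIR,
    occurrence: int = 1,
    window: float = DEFAULT_WINDOW,
    blank: float = 0.005,
) -> LinearLeak:
    """Estimate (g_leak, E_leak) from the mean currents at two voltage steps.

    g_leak = (I1 - I2) / (V1 - V2) over the last ``window`` seconds of each
    step; E_leak = V1 - I1 / g_leak (solved at the first step of the pair —
    algebraically equivalent at either, given the fitted g_leak).
    """
    v1, v2 = step_pair
    if abs(v1 - v2) <= protocol.delta_v:
        raise DegeneratePairError(
            f"step pair voltages {v1:g} and {v2:g} mV are not distinguishable"
        )
    aligned = align(trace, protocol)
    s1 = find_step(protocol, v1, occurrence)
    s2 = find_step(protocol, v2, occurrence)
    i1 = _window_mean(aligned, s1, window, blank)
    i2 = _window_mean(aligned, s2, window, blank)
    g = (i1 - i2) / (s1.voltage - s2.voltage)
    if g == 0.0:
        # flat I-V: reversal potential unidentifiable; report the step voltage
        e = s1.voltage
    else:
        e = s1.voltage - i1 / g
    return LinearLeak(
        g_leak=g,
        e_leak=e,
        step_pair=(float(v1), float(v2)),
        occurrence=occurrence,
        window=window,
    )


def subtract_leak(
    trace: CurrentTrace,
    leak: LinearLeak,
    protocol: VoltageProtocol,
) -> CurrentTrace:
    """Subtract the linear leak, evaluated at the command voltage
    sample-by-sample (ramps included)."""
    align(trace, protocol)  # raises on incompatibility
    n = min(len(trace), len(protocol.times))
    residual = trace.currents.copy()
    residual[:n] -= leak.current(protocol.voltages[:n])
    return trace.with_currents(residual)
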