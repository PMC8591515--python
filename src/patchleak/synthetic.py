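"""Seeded synthetic voltage-clamp traces with stored ground truth.

The generator emulates the statistical structure the analysis assumes:

* an Ohmic leak ``g_leak * (V - E_leak)``;
* a nonlinear, time-dependent leak component: a conductance ``g(t)`` that
  relaxes first-order, ``dg/dt = (g_inf(V) - g) / tau_nl``, toward a sigmoid
  voltage-dependent steady state ``g_inf(V) = g_max / (1 + exp(-(V - V_half)/k))``,
  carrying current ``g(t) * (V - E_nl)``.  The sign of the slope factor ``k``
  sets the polarity: ``k > 0`` (scenario "I") puts the extra conductance at
  positive voltages (superlinear I-V); ``k < 0`` (scenario "II") at negative
  voltages (sublinear, inward relaxations); scenarios "III"/"linear" force
  ``g_max = 0`` (washout: purely Ohmic).  The functional form is a
  phenomenological model of a seal conductance that changes nonlinearly and
  time-dependently with voltage — not a mechanistic crystal model;
* capacitive step-edge transients ``A_cap * (dV / 100 mV) * exp(-t/tau_cap)``
  decaying well within the 5 ms analysis blank;
* i.i.d. Gaussian noise.

Every component is stored in a :class:`GroundTruth` sidecar (they sum exactly
to the emitted current), together with the closed-form steady-state I-V, so
each pipeline stage can be verified by parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

from .errors import ParameterError
from .protocol import VoltageProtocol
from .traceio import CurrentTrace, TraceMeta

#: fields drawn on a log-normal in cohorts (must stay positive)
_POSITIVE_FIELDS = {"g_leak", "g_max", "tau_nl", "a_cap", "tau_cap", "sigma"}
_DRAWABLE_FIELDS = _POSITIVE_FIELDS | {"e_leak", "v_half", "k", "e_nl"}


@dataclass(frozen=True)
class SyntheticParams:
    """Generator parameters (nS, mV, s, pA, Hz).

    Defaults give the qualitative scales of CaF2 seal-enhancer recordings:
    a ~0.5 nS (2 GOhm) Ohmic seal leak, a nonlinear component reaching a few
    tens of pA at the voltage extremes, ~0.3 s relaxations, 5 pA noise,
    5 kHz sampling.
    """

    g_leak: float = 0.5
    e_leak: float = 0.0
    g_max: float = 0.3
    v_half: float = 20.0
    k: float = 15.0
    tau_nl: float = 0.3
    e_nl: float = 0.0
    a_cap: float = 500.0  # pA per 100 mV of step edge
    tau_cap: float = 0.001
    sigma: float = 5.0
    sample_rate: float = 5000.0
    scenario: str = "custom"
    seed: int | None = None

    def __post_init__(self):
        if self.tau_nl <= 0 or self.tau_cap <= 0:
            raise ParameterError("tau_nl and tau_cap must be positive")
        if self.sigma < 0:
            raise ParameterError("sigma must be non-negative")
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be positive")


def scenario_params(scenario: str, seed: int | None = None, **overrides) -> SyntheticParams:
    """Preset parameters for the named measurement scenario.

    "I": extra conductance activated at positive voltages (k > 0).
    "II": solutions swapped — extra conductance at negative voltages (k < 0).
    "III" / "linear": fluoride washed out — purely Ohmic (g_max = 0).
    """
    presets = {
        "I": {"k": 15.0},
        "II": {"k": -15.0},
        "III": {"g_max": 0.0},
        "linear": {"g_max": 0.0},
        "custom": {},
    }
    if scenario not in presets:
        raise ParameterError(
            f"unknown scenario {scenario!r}; expected one of {sorted(presets)}"
        )
    kwargs = {**presets[scenario], **overrides}
    return SyntheticParams(scenario=scenario, seed=seed, **kwargs)


def g_inf(v_mv, params: SyntheticParams) -> np.ndarray:
    """Steady-state nonlinear conductance (nS) at voltage ``v_mv``."""
    v = np.asarray(v_mv, dtype=float)
    if params.g_max == 0.0 or params.scenario in ("III", "linear"):
        return np.zeros_like(v)
    return params.g_max / (1.0 + np.exp(-(v - params.v_half) / params.k))


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-sample decomposition of a generated trace."""

    params: SyntheticParams
    linear: np.ndarray
    nonlinear: np.ndarray
    capacitive: np.ndarray
    noise: np.ndarray
    g_state: np.ndarray  # nonlinear conductance trajectory (nS)

    def total(self) -> np.ndarray:
        return self.linear + self.nonlinear + self.capacitive + self.noise

    def steady_state_iv(self, v_mv) -> np.ndarray:
        """Closed-form asymptotic current at a held voltage (pA)."""
        v = np.asarray(v_mv, dtype=float)
        p = self.params
        return p.g_leak * (v - p.e_leak) + g_inf(v, p) * (v - p.e_nl)

    def nonlinear_steady_state(self, v_mv) -> np.ndarray:
        v = np.asarray(v_mv, dtype=float)
        return g_inf(v, self.params) * (v - self.params.e_nl)

    def params_json(self) -> str:
        return json.dumps(asdict(self.params), indent=2)


def generate_trace(
    protocol: VoltageProtocol,
    params: SyntheticParams,
    trace_id: str = "synthetic",
) -> tuple[CurrentTrace, GroundTruth]:
    """Generate one seeded trace on the protocol's own time base.

    The conductance state starts at ``g_inf(holding_voltage)`` and follows
    first-order relaxation toward ``g_inf(V(t))`` — an exponential-integrator
    recursion at the sampling interval, which is exact within every
    constant-voltage segment and a per-sample explicit step during ramps.
    Identical seeds give bit-identical traces.
    """
    v = protocol.voltages
    dt = protocol.dt
    p = params

    linear = p.g_leak * (v - p.e_leak)

    ginf_t = g_inf(v, p)
    alpha = np.exp(-dt / p.tau_nl)
    g_hold = float(g_inf(np.array([protocol.holding_voltage]), p)[0])
    # g[n] = alpha*g[n-1] + (1-alpha)*ginf[n], g[-1] = g_inf(holding)
    g_state, _ = lfilter([1.0 - alpha], [1.0, -alpha], ginf_t, zi=np.array([alpha * g_hold]))
    nonlinear = g_state * (v - p.e_nl)

    capacitive = np.zeros_like(v)
    if p.a_cap != 0.0:
        edges = np.flatnonzero(np.abs(np.diff(v)) > 5.0) + 1
        n_decay = int(np.ceil(10.0 * p.tau_cap / dt)) + 1
        kernel = np.exp(-np.arange(n_decay) * dt / p.tau_cap)
        for idx in edges:
            dv = v[idx] - v[idx - 1]
            stop = min(idx + n_decay, len(v))
            capacitive[idx:stop] += p.a_cap * (dv / 100.0) * kernel[: stop - idx]

    rng = np.random.default_rng(p.seed)
    noise = rng.normal(0.0, p.sigma, size=len(v)) if p.sigma > 0 else np.zeros_like(v)

    truth = GroundTruth(
        params=p,
        linear=linear,
        nonlinear=nonlinear,
        capacitive=capacitive,
        noise=noise,
        g_state=g_state,
    )
    meta = TraceMeta(
        id=trace_id,
        scenario=p.scenario,
        extras={"seed": str(p.seed)} if p.seed is not None else {},
    )
    trace = CurrentTrace(times=protocol.times.copy(), currents=truth.total(), meta=meta)
    return trace, truth


DEFAULT_COHORT_CV: Mapping[str, float] = {
    "g_leak": 0.2,
    "e_leak": 5.0,  # |mean| ~ 0: interpreted as an absolute SD in mV
    "g_max": 0.2,
    "tau_nl": 0.1,
}


def generate_cohort(
    protocol: VoltageProtocol,
    n: int,
    params: SyntheticParams,
    cv: Mapping[str, float] | None = DEFAULT_COHORT_CV,
    seed: int | None = None,
    id_prefix: str = "trace",
) -> list[tuple[CurrentTrace, GroundTruth]]:
    """Generate ``n`` recordings with cell-to-cell parameter variation.

    Per-recording parameters are drawn around ``params`` with the given
    coefficients of variation (log-normal for positive-definite fields,
    normal otherwise; for fields whose mean magnitude is < 1e-12 the stated
    spread is an absolute SD).  Each recording uses an independent substream
    spawned from the master seed by recording index, so cohorts are
    reproducible and order-independent.
    """
    if n < 1:
        raise ParameterError(f"cohort size must be >= 1, got {n}")
    cv = dict(cv or {})
    for name, c in cv.items():
        if name not in _DRAWABLE_FIELDS:
            raise ParameterError(f"unknown cohort parameter field {name!r}")
        if c < 0:
            raise ParameterError(f"negative CV for field {name!r}: {c}")
    out = []
    width = max(len(str(n - 1)), 3)
    for i in range(n):
        ss = np.random.SeedSequence(entropy=0 if seed is None else seed, spawn_key=(i,))
        child_seeds = ss.generate_state(2)
        rng = np.random.default_rng(child_seeds[0])
        draws = {}
        for name, c in cv.items():
            mean = getattr(params, name)
            if c == 0:
                continue
            if abs(mean) < 1e-12:
                draws[name] = float(rng.normal(mean, c))
            elif name in _POSITIVE_FIELDS:
                s_ln = np.sqrt(np.log1p(c * c))
                mu_ln = np.log(abs(mean)) - 0.5 * s_ln * s_ln
                draws[name] = float(np.sign(mean) * rng.lognormal(mu_ln, s_ln))
            else:
                draws[name] = float(rng.normal(mean, abs(mean) * c))
        p_i = replace(params, seed=int(child_seeds[1] % (2**31)), **draws)
        out.append(generate_trace(protocol, p_i, trace_id=f"{id_prefix}_{i:0{width}d}"))
    return out


# ---------------------------------------------------------------------------
# protocol emulation
# ---------------------------------------------------------------------------

def staircase_protocol(
    step_duration: float = 1.0,
    hold_duration: float = 0.5,
    ramp_duration: float = 0.5,
    sample_rate: float = 5000.0,
    holding_voltage: float = 0.0,
) -> VoltageProtocol:
    """A staircase-style command waveform for simulation and testing.

    Emulates the structure of the staircase voltage protocol used with
    automated patch platforms: holding at 0 mV, a ramp down to -120 mV, a
    staircase of constant-voltage steps spanning -120..+60 mV (including the
    -80/-40 mV pair used for leak estimation, two separate +40 mV steps and
    a +60 mV step), and a ramp back to holding.  Step durations are
    parameters, not measurements of any particular instrument protocol.
    """
    dt = 1.0 / sample_rate
    segs: list[tuple[str, float, float, float]] = []  # kind, v0, v1, duration
    segs.append(("step", holding_voltage, holding_voltage, hold_duration))
    segs.append(("ramp", holding_voltage, -120.0, ramp_duration))
    for v in (-120.0, -100.0, -80.0, -60.0, -40.0, -20.0, 0.0, 40.0, 0.0, 40.0, 60.0):
        segs.append(("step", v, v, step_duration))
    segs.append(("ramp", 60.0, holding_voltage, ramp_duration))
    segs.append(("step", holding_voltage, holding_voltage, hold_duration))

    chunks = []
    for kind, v0, v1, dur in segs:
        m = int(round(dur * sample_rate))
        if kind == "step":
            chunks.append(np.full(m, v0))
        else:
            # ramp sampled on [0, dur): endpoint belongs to the next segment
            chunks.append(v0 + (v1 - v0) * np.arange(m) / m)
    voltages = np.concatenate(chunks)
    times = np.arange(len(voltages)) * dt
    return VoltageProtocol.from_samples(times, voltages)


def save_ground_truth(truth: GroundTruth, path) -> None:
    """JSON sidecar: generator parameters + closed-form steady-state I-V
    evaluated on a voltage grid (components themselves live in memory only)."""
    grid = np.arange(-120.0, 61.0, 20.0)
    payload = {
        "params": asdict(truth.params),
        "steady_state_iv": {
            "voltage_mV": grid.tolist(),
            "current_pA": truth.steady_state_iv(grid).tolist(),
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
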