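"""Model/Results facade over the leak-analysis pipeline.

`LeakCurrentModel` holds one recording plus its analysis configuration;
`fit()` runs linear-leak estimation, per-step exponential fits and I-V
normalization, returning a `LeakCurrentResults` with the estimates, their
diagnostics, a text `summary()`, serialization and quick-look plots.
Cohorts of results aggregate via :func:`aggregate_results`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import ivcurve as _iv
from . import kinetics as _kin
from . import leak as _leak
from .errors import StepNotFoundError
from .ivcurve import CohortSummary, IVCurve
from .kinetics import StepFit
from .leak import LinearLeak
from .protocol import VoltageProtocol, load_protocol
from .traceio import CurrentTrace, load_trace


class LeakCurrentModel:
    """Leak-current model of one voltage-clamp recording.

    Parameters
    ----------
    trace : CurrentTrace
        The recording (pA, outward positive).
    protocol : VoltageProtocol
        The command protocol the recording was made under.
    leak_steps : (float, float)
        Step-voltage pair for the Ohmic fit (default (-80, -40) mV; use
        (+40, +60) mV when the nonlinearity sits at negative voltages).
    leak_occurrence : int
        Which repetition of the pair's steps to use (1-based).
    leak_window : float
        Averaging window at the end of each leak step (s).
    blank : float
        Post-edge interval excluded from every step fit (s).
    v_range : (float, float)
        Inclusive voltage range of the I-V curve (mV).
    """

    def __init__(
        self,
        trace: CurrentTrace,
        protocol: VoltageProtocol,
        *,
        leak_steps: tuple[float, float] = _leak.DEFAULT_STEP_PAIR,
        leak_occurrence: int = 1,
        leak_window: float = _leak.DEFAULT_WINDOW,
        blank: float = _kin.DEFAULT_BLANK,
        v_range: tuple[float, float] = _iv.DEFAULT_V_RANGE,
    ):
        self.trace = trace
        self.protocol = protocol
        self.leak_steps = tuple(float(v) for v in leak_steps)
        self.leak_occurrence = int(leak_occurrence)
        self.leak_window = float(leak_window)
        self.blank = float(blank)
        self.v_range = (min(v_range), max(v_range))

    @classmethod
    def from_csv(
        cls,
        trace_path,
        protocol_path,
        time_unit: str = "s",
        **kwargs,
    ) -> "LeakCurrentModel":
        """Build a model from the CSV interchange files."""
        protocol = load_protocol(protocol_path, time_unit=time_unit)
        trace = load_trace(trace_path)
        return cls(trace, protocol, **kwargs)

    def fit(self) -> "LeakCurrentResults":
        leak = _leak.estimate_linear_leak(
            self.trace,
            self.protocol,
            step_pair=self.leak_steps,
            occurrence=self.leak_occurrence,
            window=self.leak_window,
            blank=self.blank,
        )
        fits = _kin.fit_all_steps(self.trace, self.protocol, blank=self.blank)
        raw = _iv.build_iv(
            fits, v_range=self.v_range, recording_id=self.trace.meta.id
        )
        iv = _iv.normalize_iv(raw, leak)
        return LeakCurrentResults(model=self, leak=leak, step_fits=fits, iv=iv)


@dataclass
class LeakCurrentResults:
    """Fitted leak parameters, per-step kinetics and the normalized I-V."""

    model: LeakCurrentModel
    leak: LinearLeak
    step_fits: list[StepFit]
    iv: IVCurve

    @property
    def recording_id(self) -> str:
        return self.model.trace.meta.id

    @property
    def n_excluded(self) -> int:
        return self.iv.n_excluded

    def deviations(self) -> pd.DataFrame:
        """Per-point nonlinearity profile (normalized deviation from the
        leak line)."""
        return _iv.nonlinearity_profile(self.iv, self.leak)

    def time_constant(self, voltage: float = 40.0, occurrence: int = 1) -> float:
        """Tau of the selected step (s); NaN if that fit is unusable."""
        taus, _ = _kin.collect_time_constants(
            [self.step_fits], voltage=voltage, occurrence=occurrence
        )
        return taus[0] if taus else float("nan")

    def fits_frame(self) -> pd.DataFrame:
        return _kin.fits_to_frame(self.step_fits, self.recording_id)

    def iv_frame(self) -> pd.DataFrame:
        return self.iv.to_frame()

    def subtracted_trace(self) -> CurrentTrace:
        """The recording with the fitted linear leak removed."""
        return _leak.subtract_leak(self.model.trace, self.leak, self.model.protocol)

    def summary(self) -> str:
        lines = []
        lines.append("Leak-current analysis".center(64))
        lines.append("=" * 64)
        lines.append(f"{'Recording:':<22}{self.recording_id}")
        lines.append(f"{'Scenario:':<22}{self.model.trace.meta.scenario}")
        lines.append(f"{'Protocol steps:':<22}{len(self.model.protocol.steps)}")
        lines.append("-" * 64)
        lines.append(
            f"{'g_leak:':<22}{self.leak.g_leak: .5g} nS"
            f"   (R_seal = {1e3 / self.leak.g_leak if self.leak.g_leak else float('inf'):.4g} MOhm)"
        )
        lines.append(f"{'E_leak:':<22}{self.leak.e_leak: .5g} mV")
        lines.append(
            f"{'Leak step pair:':<22}{self.leak.step_pair[0]:g}/"
            f"{self.leak.step_pair[1]:g} mV (occ {self.leak.occurrence}, "
            f"window {self.leak.window:g} s)"
        )
        lines.append("-" * 64)
        lines.append(
            f"{'V (mV)':>8} {'occ':>4} {'a (pA)':>10} {'tau (s)':>10} "
            f"{'c (pA)':>10} {'rmse':>8} {'ok':>3}"
        )
        for f in self.step_fits:
            v = f.voltage
            occ = f.step.occurrence if f.step is not None else -1
            flag = "y" if f.converged else "n"
            if f.converged and not f.tau_reliable:
                flag = "y*"
            lines.append(
                f"{v:>8.1f} {occ:>4d} {f.a:>10.3g} {f.tau:>10.3g} "
                f"{f.c:>10.4g} {f.rmse:>8.3g} {flag:>3}"
            )
        lines.append("-" * 64)
        lines.append("y* = converged but amplitude within noise (tau unreliable)")
        return "\n".join(lines)

    def save(self, outdir) -> dict[str, Path]:
        """Write leak JSON, step-fit CSV and I-V CSV under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rid = self.recording_id
        paths = {
            "leak": outdir / f"{rid}_leak.json",
            "fits": outdir / f"{rid}_fits.csv",
            "iv": outdir / f"{rid}_iv.csv",
        }
        paths["leak"].write_text(self.leak.to_json() + "\n", encoding="utf-8")
        self.fits_frame().to_csv(paths["fits"], index=False, float_format="%.6g")
        self.iv_frame().to_csv(paths["iv"], index=False, float_format="%.6g")
        return paths

    # -- plotting -----------------------------------------------------------
    def plot_iv(self, ax=None):
        """Normalized steady-state I-V with the leak line (quick look)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        v = self.iv.voltages
        y = [p.normalized for p in self.iv.points]
        ax.plot(v, y, "x", color="tab:blue", label="steady state")
        grid = np.linspace(*self.iv.v_range, 100)
        line = [
            _iv.normalized_leak_value(self.leak, float(g), self.iv.v_range)
            for g in grid
        ]
        ax.plot(grid, line, "--", color="tab:orange", label="linear leak")
        ax.set_xlabel("Voltage (mV)")
        ax.set_ylabel("Normalized current")
        ax.legend()
        return ax

    def plot_trace(self, ax=None):
        """Recording with the fitted leak line current overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.trace.times
        ax.plot(t, self.model.trace.currents, lw=0.5, color="tab:blue")
        ax.plot(
            t,
            self.leak.current(self.model.protocol.voltages[: len(t)]),
            "--",
            color="tab:orange",
        )
        ax.set_xlabel("Time (s)")
        ax.set_ylabel("Current (pA)")
        return ax


def fit_cohort(
    traces: Sequence[CurrentTrace],
    protocol: VoltageProtocol,
    **model_kwargs,
) -> list[LeakCurrentResults]:
    """Fit every recording of a cohort with shared settings."""
    return [
        LeakCurrentModel(tr, protocol, **model_kwargs).fit() for tr in traces
    ]


def aggregate_results(results: Sequence[LeakCurrentResults]) -> CohortSummary:
    """Range-and-quartile cohort summary of the normalized I-V curves."""
    return _iv.aggregate_cohort([r.iv for r in results])
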