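# Methods

## Analysis model

The package analyses whole-cell (or no-cell) voltage-clamp recordings made
under a step-and-ramp command protocol. Three quantities are extracted per
recording.

**Linear (Ohmic) leak.** The seal leak is modelled as
`I_leak = g_leak (V − E_leak)` with `g_leak` in nS, voltages in mV and
currents in pA (outward positive), so the product needs no unit conversion.
`g_leak` is the ratio of the mean-current difference to the voltage
difference between two constant-voltage steps, the means taken over the last
`window` (default 0.5 s) of each step; `E_leak` then follows algebraically
from the first step of the pair (the choice of step is immaterial given the
fitted slope). The default pair is (−80, −40) mV. When the nonlinear
component sits at negative voltages (scenario II below) the caller selects a
high-voltage pair, (+40, +60) mV, so the fit is not contaminated. Steps
shorter than `window + blank` fall back to all post-blank samples with a
warning rather than failing.

**Per-step relaxation kinetics.** Each step's current is fitted with
`I(t) = a exp(−(t − t₀)/τ) + c` over `[t₀ + blank, t_end)`; the first
`blank = 5 ms` are discarded to avoid capacitive spikes. `c` is the
steady-state estimate used for the I-V curve; `τ` is the relaxation time
constant.

**Normalized steady-state I-V.** Per recording, the fitted `c` of every
converged step fit with voltage in [−120, +40] mV (inclusive; repeated
voltages contribute separate points) is normalized as
`(c − L_min)/(L_max − L_min)`, where `L_min`, `L_max` are the extrema of
that recording's own fitted leak line over the range. The leak line itself
therefore maps exactly to 0 and 1 at the range endpoints, putting recordings
with different seal resistances and reversal potentials on a common axis.
Cohorts are summarised per voltage by min/Q1/median/Q3/max of the pooled
normalized values (linear-interpolation quartiles — stated explicitly
because boxplot conventions differ). The *nonlinearity profile* is the
per-point difference between the normalized steady state and the normalized
leak-line value: positive = superlinear (extra outward current), negative =
sublinear (extra inward current).

## Protocol segmentation

A protocol is decomposed into *steps* — maximal runs of samples staying
within ±δV (default 0.5 mV) of the run median for at least `min_duration`
(default 50 ms) — and *ramps* (everything else). Intervals are half-open
`[t_start, t_end)` with time zero at the first sample. Runs are found by
splitting at sample-to-sample jumps larger than δV and refining gradual
chunks with a left-to-right greedy median scan; the defaults keep every
staircase step while rejecting ramp samples. Each step carries a 1-based
*occurrence* counter among steps of the same voltage (matched within the
same δV), so "the first +40 mV step" is addressable. Ramps are retained for
simulation but never fitted.

A consequence of tolerance-based segmentation: a step that ends in a ramp
(rather than a jump) absorbs the first ≤ δV of the ramp (a few ms), which
perturbs window means and steady states by parts in 10³ at most. Steps
bounded by jumps are segmented exactly.

## Exponential fitting

The fit is separable (variable projection): for fixed τ the model is linear
in `(a, c)` and solved exactly by the 2×2 normal equations, with the
residual sum of squares evaluated from explicit residuals (the algebraic
shortcut suffers catastrophic cancellation on near-exact fits). The RSS is
profiled over 64 log-spaced τ values in `[10⁻⁴, 10] × window` and refined
by bounded scalar minimisation in log τ (absolute tolerance 10⁻¹² in log
space) between the best grid point's neighbours. This reduces the fit to a
1-D optimisation that is robust, fast, and by construction never worse than
any fixed τ grid within the same bounds; on noiseless exponentials it
recovers `(a, τ, c)` to better than 10⁻⁶ relative error.

Numerical conventions:

* τ is bounded above by 10× the fit window — slower relaxations are not
  identifiable from the window and would otherwise absorb noise trends.
  The flip side is that transient-free (pure-noise) steps can fit a large τ
  and extrapolate the asymptote `c` a few pA away from the window mean; this
  inflation is inherent to estimating an asymptote and is why cohort
  summaries use medians.
* If `|a| < 2σ̂` (σ̂ = residual SD), the fit is reported converged with its
  `c`, but τ is flagged *unreliable* — a time constant is meaningless
  without a transient. Collection of time constants excludes non-converged
  fits by default and counts exclusions; excluding unreliable-τ fits too is
  an option.
* Degenerate failures (non-finite profile) fall back to `c` = mean of the
  last 10% of the step, flagged non-converged.
* Constant segments yield `a = 0` exactly, `c` = the mean, τ unreliable.

## Synthetic recordings

The generator emulates the structure the analysis assumes, with exact stored
ground truth (the four components sum bit-exactly to the emitted current):

* **Ohmic leak** `g_leak (V − E_leak)`.
* **Nonlinear time-dependent leak**: a conductance g(t) relaxing first-order,
  `dg/dt = (g_inf(V) − g)/τ_nl`, toward
  `g_inf(V) = g_max / (1 + exp(−(V − V_half)/k))`, carrying
  `g(t) (V − E_nl)`. The state starts from `g_inf(holding)` and is advanced
  by an exponential-integrator recursion at the sampling interval — exact
  within constant-voltage segments, explicit per-sample stepping through
  ramps. The sigmoid/first-order form is a phenomenological model of a seal
  conductance that changes nonlinearly and time-dependently with voltage;
  it is not a mechanistic CaF₂ crystal model. The slope sign sets the
  polarity: scenario `"I"` (k = +15 mV) places the extra conductance at
  positive voltages (superlinear I-V, outward relaxation on the 0→+40 mV
  step); `"II"` (k = −15 mV) at negative voltages (sublinear, inward
  relaxations at −80…−120 mV); `"III"`/`"linear"` force `g_max = 0`
  (fluoride washout: purely Ohmic).
* **Capacitive edge transients** `A_cap (ΔV/100 mV) exp(−t/τ_cap)` at each
  command jump, with `τ_cap = 1 ms` so the 5 ms analysis blank suppresses
  them to < 1% of their amplitude.
* **Noise**: i.i.d. Gaussian, SD σ. No 1/f, line pickup, drift or
  series-resistance artefacts are modelled — passing recovery tests
  therefore demonstrates correctness of the estimators under the assumed
  noise model, not robustness to every artefact of laboratory data.

Defaults (all configurable, chosen once as qualitatively realistic scales
for seal-enhancer recordings, not as estimates of any published values):
`g_leak = 0.5 nS` (2 GΩ seal), `E_leak = 0 mV`, `g_max = 0.3 nS`,
`V_half = +20 mV`, `|k| = 15 mV`, `τ_nl = 0.3 s`, `E_nl = 0 mV`,
`A_cap = 500 pA / 100 mV`, `τ_cap = 1 ms`, `σ = 5 pA`, 5 kHz sampling.

**Cohorts.** Per-recording parameters are drawn around the means with
per-field coefficients of variation (defaults: 0.2 on `g_leak` and `g_max`,
0.1 on `τ_nl`, and 5 mV spread on `E_leak`): log-normal, mean-preserving
draws for positive-definite fields; normal draws otherwise; for fields whose
mean magnitude is below 10⁻¹² the stated spread is interpreted as an
absolute SD (a CV is undefined at zero mean). Each recording uses an
independent substream spawned from the master seed by recording index, so
cohorts are reproducible and order-independent.

**Protocol emulation.** `staircase_protocol()` builds a staircase-style
waveform — 0 mV holding, a 0.5 s ramp to −120 mV, constant steps at −120,
−100, −80, −60, −40, −20, 0, +40, 0, +40, +60 mV (two separate +40 mV
steps; the first is an 0→+40 jump), and a ramp home — emulating the
structure of the staircase protocols used on automated platforms. Step
durations are parameters (default 1 s), not measurements of any instrument
file; real protocol files load through `load_protocol` and are never
hard-coded.

## Validation study sizes

The validation suite and `scripts/acceptance.py` use: a 20-recording Ohmic
cohort (σ = 5 pA) for (g_leak, E_leak) recovery; 50 single-seed recordings
of scenario I for τ recovery; 13 / 4 / 4 recordings for the scenario
I / II / III polarity checks (matching the replicate counts the scenarios
are meant to emulate); and 100 seeded segments for the fitting-oracle
comparison. The τ-recovery study uses 8 s steps (≈ 27 τ_nl): with the
default amplitude (≈ 7 pA on the first +40 mV step) and noise, the
Cramér–Rao bound on the relative SD of τ̂ is ≈ 7% at 2 s steps — no
estimator could then put 90% of recordings within 10% — and ≈ 5.5% once the
transient and baseline are both fully resolved, which 8 s steps achieve.
Shorter-step protocols remain fine for steady-state (I-V) work; resolving τ
to 10% simply demands long steps.

## Known limitations

* Single-exponential kinetics only; no multi-exponential or drift models,
  and no automatic model selection.
* The two-point leak estimator inherits the field's assumption that both
  chosen steps are nonlinearity-free; in scenario-I-like data the residual
  nonlinear current at −40 mV (~0.2 pA at the defaults) biases E_leak by a
  fraction of a millivolt.
* Tolerance-based segmentation bleeds ≤ δV of an adjoining ramp into steps
  not bounded by jumps (see above).
* HEKA/Patchmaster and other vendor binary formats are out of scope; real
  recordings enter through the CSV dialect (`time,current`; seconds, pA;
  `# key: value` metadata comments).
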