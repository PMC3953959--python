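# Methods

## Two-state sensor model

The analytic core (`redoxkin.sensor`) treats a sensor protein as a
two-state system: a reduced form oxidized by H₂O₂ with second-order rate
constant k (M⁻¹ s⁻¹), and an oxidized form regenerated with first-order
rate constant k_off (s⁻¹) that lumps the thioredoxin/glutaredoxin
machinery. Assumptions:

- H₂O₂ is at a constant steady state during the exposure, so oxidation is
  pseudo-first-order with rate k_act = k·[H₂O₂];
- the total sensor pool is conserved (reduced + oxidized = total), so one
  fraction determines the other exactly;
- oxidation is single-step — hyperoxidation to sulfinic/sulfonic forms and
  condensation chemistry are not modeled;
- rate constants are taken as measured (mostly pH 7.4, 37 °C); temperature
  and pH caveats travel as free-text metadata on compendium entries, not as
  model corrections.

The reduced fraction follows the closed form
`f(t) = s + (f0 − s)·exp(−(k_act + k_off)t)` with `s = k_off/(k_off+k_act)`.
The response time is defined as the time to cover half of the *total*
change between the initial and asymptotic state, giving
`τ½ = ln2/(k_act + k_off)`. When the initial state is away from its
asymptote on either side this "half the gap" definition is the one
implemented; other quantiles are not offered. With both rates zero the
system has no dynamics and a response time is undefined — the functions
raise rather than returning infinity.

`reduced_fraction0` defaults to 1 (fully reduced resting sensor), which is
the state in which a response-time calculation is meaningful.

### Units and rounding

Internal computation is strictly SI (mol/L, seconds); `redoxkin.units`
converts µM/mM/min/h at the boundaries, because the source literature mixes
all of these and silent unit defaults are the classic failure mode. Report
tables round to 2 significant figures (the precision at which such rate
constants are meaningful); full precision is retained internally and
available via the `sig_figs` argument.

### Membrane gradient

Extracellular H₂O₂ sits above the intracellular concentration by a factor
set by membrane permeability and intracellular consumption; 6.8 (HeLa) is
the documented default example, but the factor is always an explicit
parameter, never assumed. Doses flagged extracellular are divided by the
factor before kinetics; rate constants fitted against extracellular doses
are multiplied by it to reference them intracellularly. The two operations
commute with fitting, which is tested.

## Competition simulator

`redoxkin.competition` integrates

```
d[H2O2]/dt  = P − Σᵢ kᵢ[Sᵢ][H2O2] − k_T[T_red][H2O2]
d[T_red]/dt = −k_T[T_red][H2O2]
```

Sinks are non-depletable by construction (enzymes are recycled, GSH is
buffered); only the target pool depletes. Target mass conservation is
structural: the oxidized amount is derived, never integrated.

The bundled example system (production 1.2×10⁻² M/s, GPx 6×10⁷ M⁻¹s⁻¹ at
2 µM, GSH 0.87 M⁻¹s⁻¹ at 5 mM, PTP1B 8.3 nM at 20 M⁻¹s⁻¹) is stiff: H₂O₂
relaxes in ~8 ms while the target half-life is ~350 s. Numerical choices:

- two modes: `qssa` (default) pins H₂O₂ at the analytic steady state
  `P/Σkᵢ[Sᵢ]` and reduces the target with the closed-form exponential,
  exploiting the ~6-order timescale separation; `full` integrates both
  variables with LSODA (rtol 1e-8, atol 1e-15 M by default, configurable)
  and exists to *measure* the quality of the approximation rather than
  assert it — the two agree on the example system's half-life to <0.1%;
- the output grid is log-spaced so both the millisecond H₂O₂ rise and the
  minutes-scale target decay are resolved;
- initial H₂O₂ defaults to 0; the system fills to steady state in tens of
  milliseconds, so any initial value at or below steady state changes the
  target half-life by well under 0.1%;
- the target's own H₂O₂ consumption may be included in the analytic steady
  state (`include_target=True`); for realistic parameters it shifts the
  result at the ~10⁻⁷ relative level, and both options are exposed so the
  claim is checkable;
- negative concentrations beyond solver tolerance abort with an error;
  within tolerance they are clamped to zero.

The half-life is read from the trajectory by linear interpolation between
the bracketing output points; on the log-spaced default grid near the
crossing this interpolation error is ~10⁻⁴ relative. The flux partition
`kᵢ[Sᵢ]/Σkⱼ[Sⱼ]` is concentration-independent (H₂O₂ cancels); pairwise
ratios are reported in log10 because "orders of magnitude" is how the
competition argument is phrased. For the bundled system the GPx/PTP1B
ratio computes to 7.2×10⁸ (log10 = 8.86), i.e. just under nine orders of
magnitude; the package reports the exact ratio.

## Dose–response estimation

`redoxkin.estimation` fits `−ln(fraction remaining) = slope·dose` by
least squares **through the origin** and returns k = slope/exposure_time.
The origin constraint follows from the model (zero dose ⇒ zero log-loss);
an unconstrained intercept mode exists for diagnostics only. The fit is
unweighted on the log scale — the implied noise model is multiplicative,
homoscedastic in the log — with inverse-variance weighting left out of v1.
Handling of degenerate points:

- zero-dose points carry no information under the origin constraint and
  are excluded from the log transform;
- fractions ≤ 0 cannot be log-transformed and are rejected with a warning;
- fractions > 1 (noise above the control) are clipped to 1 with a warning;
- fewer than 2 usable points is an error.

The standard error is the origin-constrained residual formula
`sqrt(RSS/(n−1)/Σx²)` divided by the exposure time.

The estimator assumes pure exponential decay. When a switch-off process is
actually operating the observed fractions plateau above the exponential,
and the estimator is biased low; this is demonstrated in the tests, and it
is the reason a two-parameter (k, k_off) joint fit is deliberately out of
scope — there are no quantitative switch-off data to anchor it, and the
single-slope procedure is the one used in practice on time courses where
regeneration is not yet significant.

## Synthetic data generator

`generate_synthetic_dataset` emulates a dose–response inactivation assay:
fractions follow `exp(−k·dose·t)` at the supplied doses (defaults in the
tests: k ≈ 20 M⁻¹s⁻¹-class constants, 4 doses spanning 50–500 µM, 5–10 min
exposures — the design of published PTP1B/KEAP1-style experiments), then
receive multiplicative lognormal noise with a stated coefficient of
variation. The noise has **median 1** (ln ε ~ N(0, σ), σ = √ln(1+cv²)), so
log-scale regression noise is zero-centered; a mean-1 convention would
build a small deterministic bias into every synthetic experiment. A 5% CV
is used in the recovery study (200 seeded replicates), a typical precision
for enzymatic activity assays. All randomness flows through
`numpy.random.default_rng(seed)`; the seed is recorded on the dataset.

What the generator does *not* emulate: dose-dependent error structure,
assay floor/saturation artifacts, switch-off during exposure (available
separately through the two-state model, and used in the bias
demonstration), or inter-experiment batch effects. Passing the recovery
tests therefore shows the estimator is correct under its own model, not
that real assays satisfy that model.

## Compendium and reports

The bundled compendium holds ten proteins (8 thiol, 2 metal) with rate
constants spanning 0.87 (GSH) to 2×10⁷ M⁻¹s⁻¹ (catalase), each with source
and temperature notes. PerR's constant circulates both as "~10⁵" and as
1.0×10⁵; the compendium stores 1.0×10⁵ with a note. Required-concentration
tables are computed as `ln2/(k·τ)`, converted to µM and rounded to 2
significant figures; rounding is idempotent by construction.

Reactivity classes ("low" < 10³ ≤ "intermediate" < 10⁵ ≤ "high", boundary
to the upper bin) are this package's own operationalization of the
qualitative vocabulary in the redox literature, documented as such and
overridable.

## Problem sizes

The acceptance script integrates the bundled system over 3000 s on a
400-point log grid — ~8.5 target half-lives, enough for the plateau mean
and the 0.5-crossing to be insensitive to the grid. The Monte-Carlo
recovery study uses 200 replicates of 4-point experiments, which bounds
the standard error of the mean estimate at ~0.17% of truth, an order of
magnitude below the 2% bias criterion it checks.

## Known limitations

- No spatial structure: localized H₂O₂ microdomains, compartment gradients
  and aquaporin-mediated transport are outside the model; the single
  gradient factor is a lumped stand-in for membrane permeability only.
- Switch-off is a single lumped first-order rate; saturable reductase
  kinetics would change the steady-state fraction at high oxidant load.
- The competition simulator holds sink concentrations fixed; peroxiredoxin
  hyperoxidation/inactivation feedback (the floodgate scenario) is not
  modeled.
- Rate constants measured in vitro may not equal in-cell values; the
  toolkit propagates, but cannot resolve, that uncertainty.
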