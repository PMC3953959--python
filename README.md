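# redoxkin

A kinetics toolkit for analyzing proteins that sense hydrogen peroxide.

Redox signaling works through proteins — phosphatases such as PTP1B and
Cdc25B, the KEAP1/NRF2 axis, peroxiredoxins, bacterial metal-center
regulators like PerR — whose cysteine thiolates (or metal centers) are
oxidized by H₂O₂, switching their activity. Whether a given protein can be a
*direct* sensor of an H₂O₂ signal is a quantitative question: it depends on
its second-order rate constant with H₂O₂, on the steady-state H₂O₂
concentration it actually sees (which sits behind a plasma-membrane
permeability gradient), and on how long the signal lasts. `redoxkin` makes
that arithmetic — and the simulations behind it — reproducible, for
quantitative redox biologists and modelers.

## The model

A sensor cycles between reduced and oxidized states:

```
Target_red + H2O2 → Target_ox      v = k · [H2O2] · [Target_red]
Target_ox         → Target_red     v = k_off · [Target_ox]
```

With H₂O₂ at steady state the activation step is pseudo-first-order,
k_act = k·[H₂O₂], and the reduced fraction has the closed form

```
f(t) = s + (f0 − s)·exp(−(k_act + k_off)·t),   s = k_off/(k_off + k_act)
```

The response time (time to half of the total change) is
τ½ = ln 2 / (k_act + k_off), which for a non-regenerating sensor is
τ½ = ln 2 / (k·[H₂O₂]). That one identity can be inverted three ways: given
any two of {rate constant, H₂O₂ concentration, response time}, compute the
third. It also linearizes dose–response experiments:
−ln(fraction remaining) = k·t·[H₂O₂], so the slope of a log-linear fit
through the origin, divided by exposure time, estimates k. Rate constants
fitted against extracellular doses are multiplied by the membrane gradient
factor (extracellular/intracellular concentration ratio; 6.8 in HeLa cells)
to reference them to the concentration the sensor actually sees.

The competition simulator adds the other half of the argument: H₂O₂ produced
at a constant rate is consumed overwhelmingly by abundant antioxidant sinks
(glutathione peroxidase, bulk GSH), which outcompete a slow signaling target
for H₂O₂ *flux* by ~nine orders of magnitude — and yet the target is still
half-oxidized within minutes at the resulting steady state. Consumption
share and sensing ability are different things; a good sensor reads the
signal without draining it.

## Worked example

How much H₂O₂ does PTP1B (k = 20 M⁻¹s⁻¹) need to respond within 5 minutes?

```
$ redoxkin required-dose --k 20 --tau 5 --time-units min
```

```json
"result": { "h2o2": 115.52, "units": "uM" }
```

About 120 µM intracellular steady-state H₂O₂ — far above tolerable bulk
levels, which is why a fast response through such a low-reactivity sensor
implies either a relay through a more reactive protein or a high localized
concentration. Now the competition simulation (bundled parameter set:
production 1.2×10⁻² M/s; GPx k = 6×10⁷ M⁻¹s⁻¹ at 2 µM; GSH k = 0.87 M⁻¹s⁻¹
at 5 mM; PTP1B pool 8.3 nM, k = 20 M⁻¹s⁻¹):

```
$ redoxkin simulate --t-end 3000 --mode full
```

```json
{
  "steady_state_h2o2_M": 9.999637513140148e-05,
  "target_half_life_min": 5.777952650101076,
  "flux_fractions": {
    "GPx": 0.9999637499307817,
    "GSH": 3.624868593499084e-05,
    "PTP1B": 1.383283187404248e-09
  }
}
```

PTP1B takes a ~10⁻⁹ share of the H₂O₂ flux, yet at the 10⁻⁴ M steady state
it is half-oxidized in 5.8 minutes — a typical signaling timescale. The
required-concentration table over the bundled ten-protein compendium
(`redoxkin table --format md`) shows which sensors can track fast signals:

| Protein | [H2O2] for tau = 30 s (µM) | [H2O2] for tau = 5 min (µM) | [H2O2] for tau = 1 h (µM) |
|---|---|---|---|
| GSH | 27000 | 2700 | 220 |
| Thioredoxin | 22000 | 2200 | 180 |
| PTP1B | 1200 | 120 | 9.6 |
| KEAP1 | 170 | 17 | 1.4 |
| … | | | |

Only the most reactive proteins (peroxiredoxins, catalase, PerR) can respond
to a 30-second transient at sub-micromolar H₂O₂; slow sensors work only for
long-lasting signals.

Fitting a rate constant from a dose–response CSV (columns `h2o2,fraction`):

```
$ redoxkin fit-k data.csv --dose-units uM --time 10 --time-units min --gradient 6.8
```

returns the fitted constant referenced both to the supplied doses and to the
intracellular concentration, with a standard error and residual diagnostics.

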