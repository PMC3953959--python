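"""Analytic two-state kinetics of an H2O2 sensor protein.

Model
-----
A sensor protein (a thiolate-bearing phosphatase, a peroxiredoxin, a metal
center, ...) cycles between a reduced (signal-off) and an oxidized
(signal-on) state:

* activation: ``Target_red + H2O2 -> Target_ox``, pseudo-first-order in the
  target because the H2O2 concentration is held at steady state,
  ``k_activation = k * [H2O2]`` with ``k`` the second-order rate constant
  (M^-1 s^-1);
* switch-off: ``Target_ox -> Target_red`` with first-order rate constant
  ``k_switchoff`` (s^-1), lumping the thioredoxin/glutaredoxin regeneration
  machinery.

With the total pool conserved, the reduced fraction obeys a linear ODE whose
closed form is

    f(t) = s + (f0 - s) * exp(-(k_act + k_off) * t),   s = k_off/(k_off + k_act)

and the oxidized fraction is its complement.  The response time tau_1/2 is the
time to cover half of the total change in oxidation state:
``ln(2)/(k_act + k_off)``, reducing to ``ln(2)/k_act`` when no switch-off
operates.  That last expression can be inverted for any one of
(rate constant, H2O2 concentration, response time) given the other two; those
inversions are what turn a handful of published rate constants into testable
statements about which sensors can respond within a given signal duration.

All quantities are SI (M, s); convert at the boundary with
:mod:`redoxkin.units`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SensorSpecies",
    "ExposureCondition",
    "KineticsResult",
    "activation_rate",
    "reduced_fraction",
    "oxidized_fraction",
    "response_time",
    "required_h2o2",
    "required_rate_constant",
    "steady_state_oxidized",
    "kinetics_summary",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class SensorSpecies:
    """Kinetic parameters of a two-state H2O2 sensor.

    Parameters
    ----------
    name : str
        Protein label (e.g. ``"PTP1B"``).
    rate_constant : float
        Second-order rate constant with H2O2, M^-1 s^-1.
    switchoff_rate : float, default 0
        First-order regeneration rate of the oxidized form, s^-1.
    reduced_fraction0 : float, default 1
        Reduced fraction at t = 0.  Defaults to a fully reduced resting
        sensor.
    """

    name: str
    rate_constant: float
    switchoff_rate: float = 0.0
    reduced_fraction0: float = 1.0

    def __post_init__(self) -> None:
        if self.rate_constant < 0:
            raise ValueError(f"rate_constant must be >= 0, got {self.rate_constant}")
        if self.switchoff_rate < 0:
            raise ValueError(f"switchoff_rate must be >= 0, got {self.switchoff_rate}")
        if not 0.0 <= self.reduced_fraction0 <= 1.0:
            raise ValueError(
                f"reduced_fraction0 must be in [0, 1], got {self.reduced_fraction0}"
            )


@dataclass(frozen=True)
class ExposureCondition:
    """A constant-H2O2 exposure.

    ``h2o2`` is the steady-state H2O2 concentration in M.  If
    ``extracellular`` is True, the concentration is understood as the
    extracellular one and is divided by ``gradient_factor`` (the
    extracellular/intracellular ratio imposed by membrane permeability and
    intracellular consumption; 6.8 for HeLa cells) before any kinetics.
    """

    h2o2: float
    duration: float = 0.0
    gradient_factor: float = 1.0
    extracellular: bool = False

    def __post_init__(self) -> None:
        if self.h2o2 < 0:
            raise ValueError(f"h2o2 must be >= 0, got {self.h2o2}")
        if self.duration < 0:
            raise ValueError(f"duration must be >= 0, got {self.duration}")
        if self.gradient_factor < 1:
            raise ValueError(
                f"gradient_factor must be >= 1, got {self.gradient_factor}"
            )

    @property
    def intracellular_h2o2(self) -> float:
        """Concentration seen by the sensor (gradient applied if needed)."""
        if self.extracellular:
            return self.h2o2 / self.gradient_factor
        return self.h2o2


@dataclass(frozen=True)
class KineticsResult:
    """Bundle of derived kinetic quantities for one sensor/exposure pair."""

    activation_rate: float
    reduced_fraction_t: float
    oxidized_fraction_t: float
    response_time: float
    steady_state_oxidized: float


def activation_rate(sensor: SensorSpecies, exposure: ExposureCondition) -> float:
    """Pseudo-first-order activation rate ``k * [H2O2]`` in s^-1."""
    return sensor.rate_constant * exposure.intracellular_h2o2


def _rates(sensor: SensorSpecies, exposure: ExposureCondition) -> tuple[float, float]:
    return activation_rate(sensor, exposure), sensor.switchoff_rate


def reduced_fraction(sensor: SensorSpecies, exposure: ExposureCondition) -> float:
    """Reduced fraction after ``exposure.duration`` seconds (closed form).

    With no switch-off this is the simple exponential decay
    ``f0 * exp(-k_act * t)``; with switch-off the pool relaxes toward the
    steady-state reduced fraction ``k_off/(k_off + k_act)`` with combined
    rate ``k_act + k_off``.
    """
    k_act, k_off = _rates(sensor, exposure)
    t = exposure.duration
    total = k_act + k_off
    if total == 0.0:
        return sensor.reduced_fraction0
    s = k_off / total
    return s + (sensor.reduced_fraction0 - s) * math.exp(-total * t)


def oxidized_fraction(sensor: SensorSpecies, exposure: ExposureCondition) -> float:
    """Oxidized fraction, the exact complement of :func:`reduced_fraction`."""
    return 1.0 - reduced_fraction(sensor, exposure)


def response_time(sensor: SensorSpecies, exposure: ExposureCondition) -> float:
    """Time to half of the total change in oxidation state, seconds.

    ``ln(2)/(k_act + k_off)``; with ``k_off = 0`` this is the half-life of
    the reduced pool, ``ln(2)/(k * [H2O2])``.

    Raises
    ------
    ValueError
        If both the activation and switch-off rates are zero (the sensor
        has no dynamics, so no response time exists).
    """
    k_act, k_off = _rates(sensor, exposure)
    total = k_act + k_off
    if total == 0.0:
        raise ValueError(
            "no dynamics: activation and switch-off rates are both zero"
        )
    return LN2 / total


def required_h2o2(rate_constant: float, response_time: float) -> float:
    """Steady-state [H2O2] (M) giving the requested response time.

    Inverts ``tau_1/2 = ln(2)/(k * [H2O2])`` for the concentration; this is
    the intracellular steady state a sensor with rate constant ``k`` needs
    in order to be half-oxidized after ``response_time`` seconds (no
    switch-off).
    """
    if rate_constant <= 0:
        raise ValueError(f"rate_constant must be > 0, got {rate_constant}")
    if response_time <= 0:
        raise ValueError(f"response_time must be > 0, got {response_time}")
    return LN2 / (rate_constant * response_time)


def required_rate_constant(
    h2o2: float, response_time: float, gradient_factor: float = 1.0
) -> float:
    """Rate constant (M^-1 s^-1) implied by an observed response time.

    Inverts ``tau_1/2 = ln(2)/(k * [H2O2])`` for ``k``.  If the observed
    H2O2 concentration is extracellular, pass the membrane
    ``gradient_factor``: the intracellular concentration is lower by that
    factor, so the intracellular-referenced rate constant is higher by the
    same factor.
    """
    if h2o2 <= 0:
        raise ValueError(f"h2o2 must be > 0, got {h2o2}")
    if response_time <= 0:
        raise ValueError(f"response_time must be > 0, got {response_time}")
    if gradient_factor <= 0:
        raise ValueError(f"gradient_factor must be > 0, got {gradient_factor}")
    return LN2 / (h2o2 * response_time) * gradient_factor


def steady_state_oxidized(sensor: SensorSpecies, exposure: ExposureCondition) -> float:
    """Steady-state oxidized fraction ``1 - k_off/(k_off + k_act)``."""
    k_act, k_off = _rates(sensor, exposure)
    total = k_act + k_off
    if total == 0.0:
        raise ValueError(
            "no dynamics: activation and switch-off rates are both zero"
        )
    return 1.0 - k_off / total


def kinetics_summary(sensor: SensorSpecies, exposure: ExposureCondition) -> KineticsResult:
    """Evaluate all derived quantities for one sensor under one exposure."""
    f_red = reduced_fraction(sensor, exposure)
    return KineticsResult(
        activation_rate=activation_rate(sensor, exposure),
        reduced_fraction_t=f_red,
        oxidized_fraction_t=1.0 - f_red,
        response_time=response_time(sensor, exposure),
        steady_state_oxidized=steady_state_oxidized(sensor, exposure),
    )
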