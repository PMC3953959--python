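"""Bundled rate-constant compendium and required-concentration tables.

Ships a small curated compendium of second-order rate constants for the
reaction of H2O2 with thiol and metal sensor proteins (spanning nearly eight
orders of magnitude, from bulk GSH at 0.87 M^-1 s^-1 to catalase at
2e7 M^-1 s^-1) and builds the table that makes the sensing argument
concrete: the intracellular steady-state H2O2 concentration each protein
would need in order to be half-oxidized within a given response time,
``[H2O2] = ln(2)/(k * tau)``.  Reading across that table tells you which
sensors are fast enough for a 30-second transient and which only work for
hour-long signals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib.resources import files
from typing import Sequence

from .sensor import required_h2o2
from .units import from_molar, from_seconds, round_sig

__all__ = [
    "CompendiumEntry",
    "ResponseTable",
    "builtin_compendium",
    "generate_response_table",
    "classify_reactivity",
    "DEFAULT_RESPONSE_TIMES",
    "DEFAULT_REACTIVITY_THRESHOLDS",
]

#: default response times: 30 s, 5 min, 1 h (in seconds)
DEFAULT_RESPONSE_TIMES: tuple[float, ...] = (30.0, 300.0, 3600.0)

#: reactivity class boundaries in M^-1 s^-1 (artifact convention: the
#: literature speaks of "high" and "low" reactivity without quantifying;
#: these cutoffs are this package's own, documented and overridable)
DEFAULT_REACTIVITY_THRESHOLDS: tuple[float, float] = (1e3, 1e5)


@dataclass(frozen=True)
class CompendiumEntry:
    """One protein's rate constant with provenance metadata."""

    name: str
    rate_constant: float  # M^-1 s^-1
    category: str  # "thiol-protein" | "metal-protein"
    source_note: str = ""
    temperature_note: str = ""

    def __post_init__(self) -> None:
        if self.rate_constant <= 0:
            raise ValueError(f"rate_constant must be > 0, got {self.rate_constant}")


@dataclass(frozen=True)
class ResponseTable:
    """Required-[H2O2] matrix: entries x response times, cells in µM."""

    entries: tuple[str, ...]
    response_times: tuple[float, ...]  # s
    cells: tuple[tuple[float, ...], ...]  # µM, rounded to `sig_figs`
    sig_figs: int

    def to_markdown(self) -> str:
        def fmt_time(t: float) -> str:
            if t % 3600 == 0 and t >= 3600:
                return f"{from_seconds(t, 'h'):g} h"
            if t % 60 == 0 and t >= 60:
                return f"{from_seconds(t, 'min'):g} min"
            return f"{t:g} s"

        header = "| Protein | " + " | ".join(
            f"[H2O2] for tau = {fmt_time(t)} (µM)" for t in self.response_times
        ) + " |"
        sep = "|" + "---|" * (len(self.response_times) + 1)
        rows = [
            "| " + name + " | " + " | ".join(f"{c:g}" for c in row) + " |"
            for name, row in zip(self.entries, self.cells)
        ]
        return "\n".join([header, sep, *rows])

    def to_csv(self) -> str:
        header = "name," + ",".join(f"h2o2_uM_tau_{t:g}s" for t in self.response_times)
        rows = [
            name + "," + ",".join(f"{c:g}" for c in row)
            for name, row in zip(self.entries, self.cells)
        ]
        return "\n".join([header, *rows]) + "\n"


def builtin_compendium() -> list[CompendiumEntry]:
    """Load the bundled 10-protein compendium (8 thiol, 2 metal proteins)."""
    with files("redoxkin.data").joinpath("sensor_compendium.json").open() as fh:
        raw = json.load(fh)
    entries = [
        CompendiumEntry(
            name=e["name"],
            rate_constant=float(e["rate_constant"]),
            category=e["category"],
            source_note=e.get("source_note", ""),
            temperature_note=e.get("temperature_note", ""),
        )
        for e in raw["entries"]
    ]
    names = [e.name for e in entries]
    if len(set(names)) != len(names):
        raise ValueError("compendium entry names must be unique")
    return entries


def generate_response_table(
    entries: Sequence[CompendiumEntry] | None = None,
    response_times: Sequence[float] = DEFAULT_RESPONSE_TIMES,
    sig_figs: int = 2,
) -> ResponseTable:
    """Required steady-state [H2O2] (µM) per entry and response time.

    Each cell is ``ln(2)/(k * tau)`` converted to µM and rounded to
    ``sig_figs`` significant figures (full precision is available by
    passing a large ``sig_figs``).
    """
    if entries is None:
        entries = builtin_compendium()
    entries = list(entries)
    if not entries:
        raise ValueError("entries must be non-empty")
    times = tuple(float(t) for t in response_times)
    if any(t <= 0 for t in times):
        raise ValueError("response times must be > 0")
    cells = tuple(
        tuple(
            round_sig(from_molar(required_h2o2(e.rate_constant, t), "uM"), sig_figs)
            for t in times
        )
        for e in entries
    )
    return ResponseTable(
        entries=tuple(e.name for e in entries),
        response_times=times,
        cells=cells,
        sig_figs=sig_figs,
    )


def classify_reactivity(
    entry: CompendiumEntry | float,
    thresholds: tuple[float, float] = DEFAULT_REACTIVITY_THRESHOLDS,
) -> str:
    """Bin a rate constant into "low" / "intermediate" / "high" reactivity.

    A value equal to a threshold goes to the upper bin.  The default
    cutoffs (1e3 and 1e5 M^-1 s^-1) are this package's convention for the
    qualitative vocabulary used in the redox-signaling literature.
    """
    low_cut, high_cut = thresholds
    if not low_cut < high_cut:
        raise ValueError("thresholds must be strictly increasing")
    k = entry.rate_constant if isinstance(entry, CompendiumEntry) else float(entry)
    if k >= high_cut:
        return "high"
    if k >= low_cut:
        return "intermediate"
    return "low"
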