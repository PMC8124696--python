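"""Monetary valuation of mitigation alternatives: expected monetary value
(EMV) and exponential expected utility (EU).

Each mitigation alternative (an industrial sector whose PM2.5 emissions can
be reduced) carries a health-benefit value in dollars per ton of directly
emitted PM2.5 reduced, a probability for each concentration-increase
scenario, and a probability of success under each scenario.  With the air
volume above the study region denoted ``V`` (m^3), the mass to remove under
a scenario is ``reduction (µg/m^3) × V × 1e-12`` metric tons, the scenario's
monetary value is ``success probability × $/ton × mass``, and

    EMV = Σ_i P_i · MV_i                        (risk-neutral)
    u_i = 1 − exp(−MV_i / R),  EU = Σ_i P_i · u_i   (risk tolerance R)

Everything is homogeneous of degree one in ``V``, so results are reported
per unit air volume (V = 1) unless a volume is supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .risk_structure import PROB_TOL

__all__ = [
    "MICROGRAM_TO_TON",
    "IncreaseScenario",
    "MitigationAlternative",
    "AirVolume",
    "ValuationResult",
    "mass_to_reduce",
    "scenario_monetary_value",
    "emv",
    "expected_utility",
    "valuate",
    "rank_alternatives",
    "emv_ratio",
]

#: µg -> metric ton
MICROGRAM_TO_TON = 1e-12


@dataclass(frozen=True)
class IncreaseScenario:
    """A PM2.5 concentration-increase scenario over the planning horizon.

    ``concentration_level`` is the baseline standard grown by the increase
    rate; ``reduction_needed`` is the excess over the standard that must be
    removed to return to compliance.
    """

    label: str
    increase_rate: float
    baseline_standard: float = 12.0  # annual NAAQS, µg/m³

    def __post_init__(self) -> None:
        if self.increase_rate <= 0:
            raise ValueError(f"{self.label}: increase rate must be positive")
        if self.baseline_standard <= 0:
            raise ValueError(f"{self.label}: baseline standard must be positive")

    @property
    def concentration_level(self) -> float:
        """Projected concentration, µg/m³."""
        return self.baseline_standard * (1.0 + self.increase_rate)

    @property
    def reduction_needed(self) -> float:
        """Concentration excess over the standard, µg/m³."""
        return self.concentration_level - self.baseline_standard


@dataclass(frozen=True)
class AirVolume:
    """Volume of air above the study region, m³ (symbolic scale factor)."""

    V: float = 1.0

    def __post_init__(self) -> None:
        if self.V <= 0:
            raise ValueError("air volume must be positive")


@dataclass(frozen=True)
class MitigationAlternative:
    """A sector that can be invested in to reduce PM2.5 emissions.

    Parameters
    ----------
    name
        Sector label.
    dollars_per_ton
        Monetized health benefit per ton of directly emitted PM2.5 reduced
        (2010 USD/ton).
    scenario_probability
        Probability of each concentration-increase scenario for this sector;
        must sum to 1 (override with ``strict=False`` for verbatim published
        tables).
    success_probability
        Probability the investment succeeds under each scenario.
    """

    name: str
    dollars_per_ton: float
    scenario_probability: dict[str, float]
    success_probability: dict[str, float]
    strict: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "scenario_probability",
            {k: float(v) for k, v in self.scenario_probability.items()},
        )
        object.__setattr__(
            self, "success_probability",
            {k: float(v) for k, v in self.success_probability.items()},
        )
        if self.dollars_per_ton <= 0:
            raise ValueError(f"{self.name}: dollars_per_ton must be positive")
        for label, p in {**self.scenario_probability, **self.success_probability}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}/{label}: probability {p} outside [0, 1]")
        total = sum(self.scenario_probability.values())
        if self.strict and abs(total - 1.0) > PROB_TOL:
            raise ValueError(
                f"{self.name}: scenario probabilities sum to {total}, not 1 "
                "(pass strict=False to accept verbatim table values)"
            )


@dataclass(frozen=True)
class ValuationResult:
    """EMV/EU valuation of one alternative at a given volume and risk tolerance."""

    name: str
    monetary_values: dict[str, float]  # per scenario, USD
    emv: float
    utilities: dict[str, float]  # per scenario, dimensionless
    eu: float
    risk_tolerance: float
    aggregate_utility: float  # U(EMV) = 1 - exp(-EMV/R)


def mass_to_reduce(reduction_needed: float, volume: AirVolume | float = 1.0) -> float:
    """Mass of PM2.5 to remove, metric tons: ``reduction × V × 1e-12``.

    ``reduction_needed`` in µg/m³, ``volume`` in m³.
    """
    V = volume.V if isinstance(volume, AirVolume) else float(volume)
    if reduction_needed <= 0:
        raise ValueError("reduction_needed must be positive")
    if V <= 0:
        raise ValueError("volume must be positive")
    return reduction_needed * V * MICROGRAM_TO_TON


def scenario_monetary_value(
    alt: MitigationAlternative,
    scenario: IncreaseScenario,
    volume: AirVolume | float = 1.0,
) -> float:
    """Monetary value of the alternative under one scenario, USD:
    ``success probability × $/ton × mass to reduce``."""
    if scenario.label not in alt.success_probability:
        raise KeyError(f"{alt.name}: no success probability for scenario {scenario.label!r}")
    mass = mass_to_reduce(scenario.reduction_needed, volume)
    return alt.success_probability[scenario.label] * alt.dollars_per_ton * mass


def emv(
    alt: MitigationAlternative,
    scenarios: Sequence[IncreaseScenario],
    volume: AirVolume | float = 1.0,
) -> float:
    """Expected monetary value: scenario-probability-weighted sum of the
    per-scenario monetary values."""
    _check_scenarios(alt, scenarios)
    return float(
        sum(
            alt.scenario_probability[s.label] * scenario_monetary_value(alt, s, volume)
            for s in scenarios
        )
    )


def expected_utility(
    alt: MitigationAlternative,
    scenarios: Sequence[IncreaseScenario],
    volume: AirVolume | float = 1.0,
    risk_tolerance: float = 100.0,
    mode: Literal["per_scenario", "aggregate"] = "per_scenario",
) -> float:
    """Exponential expected utility at risk tolerance ``R``.

    In the default ``per_scenario`` mode each scenario's monetary value is
    mapped through ``u = 1 − exp(−MV/R)`` and the utilities are
    probability-weighted.  ``aggregate`` mode instead applies the utility
    function once to the EMV; the two agree to first order when every
    ``MV/R`` is small.
    """
    if risk_tolerance <= 0:
        raise ValueError("risk tolerance R must be positive")
    if mode == "aggregate":
        return -math.expm1(-emv(alt, scenarios, volume) / risk_tolerance)
    _check_scenarios(alt, scenarios)
    return float(
        sum(
            alt.scenario_probability[s.label]
            * -math.expm1(-scenario_monetary_value(alt, s, volume) / risk_tolerance)
            for s in scenarios
        )
    )


def valuate(
    alt: MitigationAlternative,
    scenarios: Sequence[IncreaseScenario],
    volume: AirVolume | float = 1.0,
    risk_tolerance: float = 100.0,
) -> ValuationResult:
    """Full EMV/EU valuation of one alternative."""
    mvs = {s.label: scenario_monetary_value(alt, s, volume) for s in scenarios}
    utils = {
        lbl: -math.expm1(-mv / risk_tolerance) for lbl, mv in mvs.items()
    }
    e = emv(alt, scenarios, volume)
    return ValuationResult(
        name=alt.name,
        monetary_values=mvs,
        emv=e,
        utilities=utils,
        eu=float(sum(alt.scenario_probability[lbl] * u for lbl, u in utils.items())),
        risk_tolerance=risk_tolerance,
        aggregate_utility=-math.expm1(-e / risk_tolerance),
    )


def rank_alternatives(
    valuations: Sequence[ValuationResult],
    criterion: Literal["emv", "eu"] = "emv",
    tie_tol: float = 1e-15,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Alternatives in descending order of EMV or EU.

    Returns ``(names, ties)``; ``ties`` lists pairs whose criterion values
    differ by at most ``tie_tol`` (input order is preserved among ties).
    """
    if not valuations:
        raise ValueError("need at least one valuation to rank")
    key = (lambda v: v.emv) if criterion == "emv" else (lambda v: v.eu)
    order = sorted(valuations, key=key, reverse=True)
    ties = [
        (a.name, b.name)
        for a, b in zip(order, order[1:])
        if abs(key(a) - key(b)) <= tie_tol
    ]
    return [v.name for v in order], ties


def emv_ratio(
    a: str, b: str, valuations: Sequence[ValuationResult]
) -> tuple[float, float]:
    """``EMV(a) / EMV(b)``, returned as ``(full precision, 2 s.f.)``."""
    by_name = {v.name: v for v in valuations}
    denom = by_name[b].emv
    if denom == 0:
        raise ZeroDivisionError(f"EMV({b}) is zero")
    ratio = by_name[a].emv / denom
    return ratio, float(f"{ratio:.2g}")


def _check_scenarios(
    alt: MitigationAlternative, scenarios: Sequence[IncreaseScenario]
) -> None:
    labels = [s.label for s in scenarios]
    missing = [l for l in labels if l not in alt.scenario_probability]
    if missing:
        raise KeyError(f"{alt.name}: no scenario probability for {missing}")
    total = sum(alt.scenario_probability[l] for l in labels)
    if alt.strict and abs(total - 1.0) > PROB_TOL:
        raise ValueError(
            f"{alt.name}: probabilities over supplied scenarios sum to {total}, not 1"
        )
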