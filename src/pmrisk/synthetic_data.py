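"""Random but structurally valid inputs for every pipeline stage, plus the
packaged LA-LBMA case study.

The generators emulate the structure of the case-study inputs — monotone
cumulative rate curves with optional elicitation bands, Dirichlet-distributed
branch and scenario probabilities, log-uniform benefit values per ton (real
sector benefits span nearly an order of magnitude), and random rank-bin MCDA
instances — so every operation can be property-tested with no external data.
Identical seed and configuration give bitwise-identical output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .decision_value import IncreaseScenario, MitigationAlternative
from .event_tree import EventTree
from .mcda import Criterion, CriterionWeights, ScoreCard
from .risk_structure import CumulativeRateCurve, FactorLevelDistribution, LevelBinning

__all__ = [
    "GeneratorConfig",
    "random_cdf",
    "random_binning",
    "random_event_tree",
    "random_decision_problem",
    "random_mcda_problem",
    "la_lbma_case",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the synthetic generators.

    Defaults mirror the case-study dimensions: three risk factors with three
    levels, three mitigation alternatives over three increase scenarios,
    three criteria with four rank bins; annual increase rates up to 2%/year,
    benefit values log-uniform over $50k–$500k per ton, and uniform (unit
    concentration) Dirichlet probabilities.
    """

    seed: int = 0
    n_factors: int = 3
    n_levels: int = 3
    n_alternatives: int = 3
    n_scenarios: int = 3
    n_criteria: int = 3
    n_ranks: int = 4
    n_knots: int = 6
    rate_range: tuple[float, float] = (0.0, 0.02)
    dollars_per_ton_range: tuple[float, float] = (5e4, 5e5)
    dirichlet_concentration: float = 1.0
    band_halfwidth: float = 0.05

    def __post_init__(self) -> None:
        for name in ("n_factors", "n_levels", "n_alternatives", "n_scenarios",
                     "n_criteria", "n_ranks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_knots < 2:
            raise ValueError("n_knots must be >= 2")
        lo, hi = self.rate_range
        if not hi > lo >= 0:
            raise ValueError("rate_range must be non-degenerate and non-negative")
        lo, hi = self.dollars_per_ton_range
        if not hi > lo > 0:
            raise ValueError("dollars_per_ton_range must be positive and non-degenerate")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        if self.band_halfwidth < 0:
            raise ValueError("band_halfwidth must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _level_labels(n: int) -> tuple[str, ...]:
    if n == 3:
        return ("High", "Medium", "Low")
    return tuple(f"L{i}" for i in range(n))


def random_cdf(
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
    factor_name: str = "factor",
) -> CumulativeRateCurve:
    """Monotone cumulative rate curve from sorted uniform knots.

    Interior knot rates and probabilities are sorted uniform draws; endpoints
    are pinned to cumulative probability 0 and 1.  A symmetric band of
    half-width ``config.band_halfwidth`` (clipped to [0, 1] and pinned at the
    endpoints) is attached when the half-width is positive.
    """
    rng = config.rng() if rng is None else rng
    lo, hi = config.rate_range
    rates = np.empty(config.n_knots)
    rates[0], rates[-1] = lo, hi
    if config.n_knots > 2:
        interior = np.sort(rng.uniform(lo, hi, size=config.n_knots - 2))
        # nudge duplicates apart; rates must be strictly increasing
        eps = (hi - lo) * 1e-9
        for i in range(1, interior.size):
            if interior[i] <= interior[i - 1]:
                interior[i] = interior[i - 1] + eps
        rates[1:-1] = interior
    probs = np.empty(config.n_knots)
    probs[0], probs[-1] = 0.0, 1.0
    if config.n_knots > 2:
        probs[1:-1] = np.sort(rng.uniform(0.0, 1.0, size=config.n_knots - 2))
    band = None
    if config.band_halfwidth > 0:
        w = config.band_halfwidth
        lower = np.clip(probs - w, 0.0, 1.0)
        upper = np.clip(probs + w, 0.0, 1.0)
        lower[0], lower[-1] = 0.0, 1.0 - min(w, 1.0)
        upper[0], upper[-1] = min(w, 1.0), 1.0
        lower[0] = 0.0
        upper[-1] = 1.0
        band = (tuple(lower), tuple(upper))
    return CumulativeRateCurve(factor_name, tuple(rates), tuple(probs), band)


def random_binning(
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
    factor_name: str = "factor",
) -> LevelBinning:
    """Contiguous level binning over the configured rate range, highest
    level first (matching the High/Medium/Low convention)."""
    rng = config.rng() if rng is None else rng
    lo, hi = config.rate_range
    cuts = np.sort(rng.uniform(lo, hi, size=config.n_levels - 1)) if config.n_levels > 1 else np.array([])
    edges = np.concatenate([[lo], cuts, [hi]])
    eps = (hi - lo) * 1e-6
    for i in range(1, edges.size):
        if edges[i] <= edges[i - 1]:
            edges[i] = edges[i - 1] + eps
    labels = _level_labels(config.n_levels)
    # labels run best-to-worst from the top of the rate axis down
    intervals = {
        labels[config.n_levels - 1 - i]: (float(edges[i]), float(edges[i + 1]))
        for i in range(config.n_levels)
    }
    return LevelBinning(factor_name, labels, intervals)


def random_event_tree(
    config: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> EventTree:
    """Event tree with Dirichlet level probabilities per factor and a random
    leaf-to-category map over the level labels."""
    rng = config.rng() if rng is None else rng
    labels = _level_labels(config.n_levels)
    alpha = np.full(config.n_levels, config.dirichlet_concentration)
    factors = tuple(
        FactorLevelDistribution(
            f"factor_{i}", dict(zip(labels, rng.dirichlet(alpha)))
        )
        for i in range(config.n_factors)
    )
    categories = _level_labels(3)
    consequence_map = {
        combo: str(rng.choice(categories))
        for combo in itertools.product(*(labels for _ in range(config.n_factors)))
    }
    return EventTree(factors, consequence_map)


def random_decision_problem(
    config: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[MitigationAlternative], list[IncreaseScenario]]:
    """Alternatives and increase scenarios with Dirichlet scenario
    probabilities, uniform success probabilities and log-uniform $/ton."""
    rng = config.rng() if rng is None else rng
    labels = _level_labels(config.n_scenarios)
    # distinct, decreasing increase rates; the worst scenario is listed first
    rates = np.sort(rng.uniform(0.02, 0.5, size=config.n_scenarios))[::-1]
    scenarios = [
        IncreaseScenario(lbl, float(r)) for lbl, r in zip(labels, rates)
    ]
    lo, hi = config.dollars_per_ton_range
    alpha = np.full(config.n_scenarios, config.dirichlet_concentration)
    alternatives = [
        MitigationAlternative(
            name=f"alternative_{i}",
            dollars_per_ton=float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
            scenario_probability=dict(zip(labels, rng.dirichlet(alpha))),
            success_probability={lbl: float(rng.uniform(0.0, 1.0)) for lbl in labels},
        )
        for i in range(config.n_alternatives)
    ]
    return alternatives, scenarios


def random_mcda_problem(
    config: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[Criterion], list[ScoreCard], CriterionWeights]:
    """Random rank-bin MCDA instance: numeric criteria with contiguous bins,
    raw assessments drawn inside the binned domain, Dirichlet weights."""
    rng = config.rng() if rng is None else rng
    criteria = []
    for j in range(config.n_criteria):
        edges = np.sort(rng.uniform(0.0, 100.0, size=config.n_ranks + 1))
        eps = 1e-6
        for i in range(1, edges.size):
            if edges[i] <= edges[i - 1]:
                edges[i] = edges[i - 1] + eps
        bins = tuple(
            (float(edges[r]), float(edges[r + 1]), r + 1) for r in range(config.n_ranks)
        )
        criteria.append(Criterion(f"criterion_{j}", bins=bins))
    cards = []
    for i in range(config.n_alternatives):
        raw = {
            c.name: float(rng.uniform(c.bins[0][0], c.bins[-1][1]))
            for c in criteria
        }
        cards.append(ScoreCard.from_raw(f"alternative_{i}", raw, criteria))
    alpha = np.full(config.n_criteria, config.dirichlet_concentration)
    weights = CriterionWeights(
        dict(zip((c.name for c in criteria), rng.dirichlet(alpha)))
    )
    return criteria, cards, weights


def la_lbma_case():
    """The packaged Los Angeles – Long Beach Metro Area case study.

    Returns the fully validated :class:`~pmrisk.case_config.CaseConfiguration`
    whose verbatim blocks hold the published table values and whose derived
    blocks hold reconstructed curves and a best-effort event tree (labelled
    as such in the file).
    """
    from importlib import resources

    from .case_config import load_case

    with resources.as_file(
        resources.files("pmrisk").joinpath("data/la_lbma.yaml")
    ) as path:
        return load_case(path)
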