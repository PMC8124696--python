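"""Joint factor-level event tree, consequence distribution and conditional
risk rating.

The event tree enumerates every combination of risk-factor levels (one level
per factor, factors independent), assigns each joint path a probability
(product of the branch probabilities) and maps it to a consequence category
for the PM2.5 concentration increase (High / Medium / Low).  From the tree
we obtain

* the marginal consequence distribution (path probabilities grouped by
  category),
* both directions of conditional probability used for risk rating:
  ``P(consequence | factor level)`` and, via Bayes' rule,
  ``P(factor level | consequence)``,
* the critical risk factor: the factor most likely to be at its High level
  given that the High consequence occurred.

All conditionals are computed exactly by enumeration; trees here have at
most a few dozen leaves, so sampling is never needed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

from .risk_structure import FactorLevelDistribution, PROB_TOL

__all__ = [
    "EventTree",
    "PathOutcome",
    "ConsequenceDistribution",
    "ConditionalRiskTable",
    "enumerate_paths",
    "consequence_distribution",
    "conditional_consequence_given_factor",
    "bayes_invert",
    "select_critical_factor",
]

# A leaf's consequence: either one category, or a distribution over categories.
ConsequenceAssignment = Union[str, Mapping[str, float]]


class TreeConfigurationError(ValueError):
    """Raised when a tree's consequence map is incomplete or invalid."""


class UndefinedConditionalError(ZeroDivisionError):
    """Raised when conditioning on a zero-probability event."""


@dataclass(frozen=True)
class PathOutcome:
    """One root-to-leaf path: joint level tuple, probability, consequence."""

    levels: tuple[str, ...]
    probability: float
    consequence: str


@dataclass(frozen=True)
class ConsequenceDistribution:
    """Probability per consequence category.

    ``probabilities`` may be loaded verbatim from a published table whose
    entries do not sum exactly to 1; the recorded total is exposed rather
    than silently forced, and ``renormalized()`` returns a proper
    distribution when one is wanted.
    """

    probabilities: dict[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "probabilities", {k: float(v) for k, v in self.probabilities.items()}
        )
        for cat, p in self.probabilities.items():
            if p < -PROB_TOL or p > 1 + PROB_TOL:
                raise TreeConfigurationError(f"P({cat}) = {p} outside [0, 1]")

    @property
    def total(self) -> float:
        return float(sum(self.probabilities.values()))

    def renormalized(self) -> "ConsequenceDistribution":
        t = self.total
        return ConsequenceDistribution({k: v / t for k, v in self.probabilities.items()})

    def __getitem__(self, category: str) -> float:
        return self.probabilities[category]


@dataclass(frozen=True)
class EventTree:
    """Independent risk factors with a leaf-to-consequence assignment.

    Parameters
    ----------
    factors
        Ordered per-factor level distributions; independence is assumed, so
        a path's probability is the product of its branch probabilities.
    consequence_map
        For every joint level tuple (one level per factor, in factor order),
        either a single consequence category or a distribution over
        categories summing to 1.
    """

    factors: tuple[FactorLevelDistribution, ...]
    consequence_map: dict[tuple[str, ...], ConsequenceAssignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        norm: dict[tuple[str, ...], dict[str, float]] = {}
        for key, assignment in self.consequence_map.items():
            key = tuple(key)
            if isinstance(assignment, str):
                norm[key] = {assignment: 1.0}
            else:
                dist = {c: float(p) for c, p in assignment.items()}
                if abs(sum(dist.values()) - 1.0) > PROB_TOL:
                    raise TreeConfigurationError(
                        f"leaf {key}: category distribution does not sum to 1"
                    )
                norm[key] = dist
        object.__setattr__(self, "consequence_map", norm)
        for combo in itertools.product(*(f.levels for f in self.factors)):
            if combo not in self.consequence_map:
                raise TreeConfigurationError(f"no consequence assigned to level tuple {combo}")

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.factor_name for f in self.factors)

    @property
    def categories(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for dist in self.consequence_map.values():
            for c in dist:
                seen.setdefault(c)
        return tuple(seen)


def enumerate_paths(tree: EventTree) -> list[PathOutcome]:
    """All root-to-leaf outcomes of the tree.

    One outcome per joint level tuple and, for probabilistic leaves, per
    category with nonzero weight.  Probabilities sum to 1.
    """
    outcomes: list[PathOutcome] = []
    for combo in itertools.product(*(f.levels for f in tree.factors)):
        p_path = float(np.prod([f[lvl] for f, lvl in zip(tree.factors, combo)]))
        for category, w in tree.consequence_map[combo].items():
            if w == 0.0:
                continue
            outcomes.append(PathOutcome(combo, p_path * w, category))
    return outcomes


def consequence_distribution(tree: EventTree) -> ConsequenceDistribution:
    """Marginal consequence distribution: path probabilities grouped by category."""
    probs: dict[str, float] = {c: 0.0 for c in tree.categories}
    for path in enumerate_paths(tree):
        probs[path.consequence] += path.probability
    return ConsequenceDistribution(probs)


def conditional_consequence_given_factor(
    tree: EventTree, factor: str, level: str
) -> dict[str, float]:
    """``P(consequence = c | factor = level)`` for every category ``c``.

    Restricts the path enumeration to paths where ``factor`` takes ``level``
    and renormalizes by that level's marginal probability.

    Raises
    ------
    UndefinedConditionalError
        If the level has probability 0.
    KeyError
        If the factor or level does not exist in the tree.
    """
    names = tree.factor_names
    if factor not in names:
        raise KeyError(f"unknown factor {factor!r}; tree has {names}")
    idx = names.index(factor)
    if level not in tree.factors[idx].levels:
        raise KeyError(f"factor {factor!r} has no level {level!r}")
    p_level = tree.factors[idx][level]
    if p_level <= 0.0:
        raise UndefinedConditionalError(
            f"P({factor} = {level}) = 0; conditional is undefined"
        )
    probs = {c: 0.0 for c in tree.categories}
    for path in enumerate_paths(tree):
        if path.levels[idx] == level:
            probs[path.consequence] += path.probability
    return {c: p / p_level for c, p in probs.items()}


def bayes_invert(p_c_given_f: float, p_f: float, p_c: float) -> float:
    """Invert a conditional with Bayes' rule:
    ``P(f | c) = P(c | f) * P(f) / P(c)``.

    Inputs may come verbatim from published tables that are not exactly
    mutually consistent; a quotient exceeding 1 is therefore reported
    clipped to 1 with a warning rather than rejected.

    Raises
    ------
    UndefinedConditionalError
        If ``p_c`` is 0.
    ValueError
        If any input lies outside [0, 1].
    """
    for name, v in (("p_c_given_f", p_c_given_f), ("p_f", p_f), ("p_c", p_c)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} = {v} outside [0, 1]")
    if p_c == 0.0:
        raise UndefinedConditionalError("P(consequence) = 0; inverse conditional undefined")
    out = p_c_given_f * p_f / p_c
    if out > 1.0:
        import warnings

        warnings.warn(
            f"Bayes inversion gave {out:.6f} > 1: inputs are mutually inconsistent; "
            "clipping to 1",
            stacklevel=2,
        )
        return 1.0
    return out


@dataclass(frozen=True)
class ConditionalRiskTable:
    """Both directions of the risk-rating conditionals.

    ``forward[(factor, level)][category]`` is ``P(consequence | factor
    level)``; ``inverse[(factor, level)][category]`` is ``P(factor level |
    consequence)``.  Tables may be built from an event tree (in which case
    the two directions satisfy Bayes' identity with the marginals) or loaded
    verbatim from published values.
    """

    forward: dict[tuple[str, str], dict[str, float]]
    inverse: dict[tuple[str, str], dict[str, float]]
    factor_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.factor_order:
            seen: dict[str, None] = {}
            for f, _ in {**self.forward, **self.inverse}:
                seen.setdefault(f)
            object.__setattr__(self, "factor_order", tuple(seen))
        for table in (self.forward, self.inverse):
            for key, dist in table.items():
                for c, p in dist.items():
                    if p < -PROB_TOL or p > 1 + PROB_TOL:
                        raise TreeConfigurationError(f"{key} -> {c}: {p} outside [0, 1]")

    @classmethod
    def from_tree(cls, tree: EventTree) -> "ConditionalRiskTable":
        """Exact conditionals of an event tree, both directions, by enumeration."""
        marg = consequence_distribution(tree)
        forward: dict[tuple[str, str], dict[str, float]] = {}
        inverse: dict[tuple[str, str], dict[str, float]] = {}
        for fdist in tree.factors:
            for level in fdist.levels:
                if fdist[level] <= 0.0:
                    continue
                fwd = conditional_consequence_given_factor(tree, fdist.factor_name, level)
                forward[(fdist.factor_name, level)] = fwd
                inverse[(fdist.factor_name, level)] = {
                    c: bayes_invert(fwd[c], fdist[level], marg[c])
                    for c in tree.categories
                    if marg[c] > 0.0
                }
        return cls(forward, inverse, tree.factor_names)


def select_critical_factor(
    table: ConditionalRiskTable,
    level: str = "High",
    consequence: str = "High",
    tie_tol: float = 1e-12,
) -> tuple[str, list[str]]:
    """Critical risk factor: argmax of ``P(factor = level | consequence)``.

    Returns ``(winner, ties)`` where ``ties`` lists every factor within
    ``tie_tol`` of the maximum (including the winner when there is more than
    one); the winner is the first such factor in input order.

    Raises
    ------
    ValueError
        If the table holds no inverse conditionals for the requested
        level/consequence pair.
    """
    scores: dict[str, float] = {}
    for factor in table.factor_order:
        entry = table.inverse.get((factor, level))
        if entry is not None and consequence in entry:
            scores[factor] = entry[consequence]
    if not scores:
        raise ValueError(
            f"no inverse conditionals for level={level!r}, consequence={consequence!r}"
        )
    best = max(scores.values())
    ties = [f for f, s in scores.items() if best - s <= tie_tol]
    return ties[0], (ties if len(ties) > 1 else [])
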