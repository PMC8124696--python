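"""Multi-criteria decision analysis: rank-bin scoring, weighted additive
decision scores, and weight-sensitivity analysis over the criterion simplex.

Alternatives are assessed on criteria (e.g. investment efficiency in $M per
ton reduced, implementation difficulty as an ordinal category, time to
become effective in years).  Raw assessments fall into ordered rank bins
(rank 1 = most preferred); ranks are reflected into scores,
``score = max_rank + 1 − rank``, so higher scores are better, and the
decision score of an alternative is the weight-weighted sum of its criterion
scores:

    DS = Σ_j CW_j · S_j

Sensitivity is explored two ways: a discrete table of DS under a handful of
weight scenarios, and a continuous surface over the two-dimensional weight
simplex {(x, y): x, y ≥ 0, x + y ≤ 1} (x and y the weights of two chosen
criteria, the third weight 1 − x − y).  Because DS is affine in the weights,
pairwise preference regions are half-planes, which ``decision_boundary``
extracts in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .risk_structure import PROB_TOL

__all__ = [
    "Criterion",
    "CriterionWeights",
    "ScoreCard",
    "WeightSimplexPoint",
    "SimplexSurface",
    "DecisionBoundary",
    "rank_of",
    "rank_to_score",
    "weighted_score",
    "score_alternative",
    "discrete_sensitivity",
    "continuous_sensitivity_surface",
    "decision_boundary",
]

RawValue = Union[float, int, str]


class BinDomainError(ValueError):
    """Raised when a raw value falls in no declared bin."""


@dataclass(frozen=True)
class Criterion:
    """A decision criterion with ordered rank bins (rank 1 = best).

    Numeric criteria declare ``bins`` as ``(lo, hi, rank)`` triples, treated
    as half-open ``[lo, hi)`` with the topmost bin closed; ordinal criteria
    declare ``categories`` mapping each category label to its rank.
    """

    name: str
    bins: Optional[tuple[tuple[float, float, int], ...]] = None
    categories: Optional[dict[str, int]] = None
    unit: str = ""

    def __post_init__(self) -> None:
        if (self.bins is None) == (self.categories is None):
            raise ValueError(f"{self.name}: declare exactly one of bins / categories")
        if self.bins is not None:
            bins = tuple(
                (float(lo), float(hi), int(rank)) for lo, hi, rank in self.bins
            )
            object.__setattr__(self, "bins", bins)
            ranks = sorted(r for _, _, r in bins)
            spans = sorted((lo, hi) for lo, hi, _ in bins)
            for (_, hi_prev), (lo_next, _) in zip(spans, spans[1:]):
                if abs(hi_prev - lo_next) > 1e-12:
                    raise ValueError(f"{self.name}: bins must be contiguous and disjoint")
        else:
            cats = {str(k): int(v) for k, v in self.categories.items()}
            object.__setattr__(self, "categories", cats)
            ranks = sorted(cats.values())
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError(f"{self.name}: ranks must be consecutive from 1, got {ranks}")

    @property
    def max_rank(self) -> int:
        if self.bins is not None:
            return max(r for _, _, r in self.bins)
        return max(self.categories.values())


@dataclass(frozen=True)
class CriterionWeights:
    """Weights on the criteria; must sum to 1."""

    weights: dict[str, float]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", {k: float(v) for k, v in self.weights.items()})
        for name, w in self.weights.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"weight {name} = {w} outside [0, 1]")
        total = sum(self.weights.values())
        if abs(total - 1.0) > PROB_TOL:
            raise ValueError(f"weights sum to {total}, not 1")

    def __getitem__(self, name: str) -> float:
        return self.weights[name]


@dataclass(frozen=True)
class WeightSimplexPoint:
    """A point of the weight simplex: x and y weights on two criteria, the
    third weight implied as 1 − x − y."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0 or self.x + self.y > 1 + 1e-12:
            raise ValueError(f"({self.x}, {self.y}) outside the weight simplex")

    @property
    def z(self) -> float:
        return 1.0 - self.x - self.y


def rank_of(raw_value: RawValue, criterion: Criterion) -> int:
    """Rank bin of a raw assessment.

    Numeric bins are half-open ``[lo, hi)`` with the topmost closed, so a
    value on a shared boundary belongs to the upper bin.
    """
    if criterion.categories is not None:
        try:
            return criterion.categories[str(raw_value)]
        except KeyError:
            raise BinDomainError(
                f"{criterion.name}: category {raw_value!r} not among "
                f"{sorted(criterion.categories)}"
            ) from None
    v = float(raw_value)
    top_hi = max(hi for _, hi, _ in criterion.bins)
    for lo, hi, rank in criterion.bins:
        if lo <= v < hi or (hi == top_hi and v == hi):
            return rank
    raise BinDomainError(f"{criterion.name}: value {v} outside all declared bins")


def rank_to_score(rank: int, max_rank: int) -> int:
    """Reflect a rank into a preference score: ``score = max_rank + 1 − rank``
    (rank 1, the most preferred bin, gets the highest score)."""
    if not 1 <= rank <= max_rank:
        raise ValueError(f"rank {rank} outside 1..{max_rank}")
    return max_rank + 1 - rank


@dataclass(frozen=True)
class ScoreCard:
    """One alternative's raw assessments, ranks and scores per criterion."""

    alternative: str
    raw: dict[str, RawValue]
    ranks: dict[str, int]
    scores: dict[str, float]

    @classmethod
    def from_raw(
        cls, alternative: str, raw: Mapping[str, RawValue], criteria: Sequence[Criterion]
    ) -> "ScoreCard":
        ranks = {c.name: rank_of(raw[c.name], c) for c in criteria}
        scores = {
            c.name: float(rank_to_score(ranks[c.name], c.max_rank)) for c in criteria
        }
        return cls(alternative, dict(raw), ranks, scores)

    def decision_score(self, weights: CriterionWeights) -> float:
        return weighted_score(self.scores, weights)


def weighted_score(scores: Mapping[str, float], weights: CriterionWeights) -> float:
    """Weighted additive decision score ``DS = Σ_j CW_j · S_j``."""
    if set(scores) != set(weights.weights):
        raise KeyError(
            f"criteria mismatch: scores {sorted(scores)} vs weights "
            f"{sorted(weights.weights)}"
        )
    return float(sum(weights[name] * s for name, s in scores.items()))


def score_alternative(
    alternative: str,
    raw: Mapping[str, RawValue],
    criteria: Sequence[Criterion],
    weights: CriterionWeights,
) -> tuple[ScoreCard, float]:
    """Bin, score, and weight one alternative in a single call."""
    card = ScoreCard.from_raw(alternative, raw, criteria)
    return card, card.decision_score(weights)


def discrete_sensitivity(
    scorecards: Sequence[ScoreCard],
    weight_scenarios: Sequence[CriterionWeights],
    tie_tol: float = 1e-12,
) -> pd.DataFrame:
    """Decision scores of every alternative under each weight scenario.

    Returns a DataFrame indexed by alternative with one column per scenario,
    plus ``.attrs['argmax']`` mapping scenario label to the best alternative
    and ``.attrs['ties']`` listing scenarios whose top scores tie.
    """
    if not weight_scenarios:
        raise ValueError("need at least one weight scenario")
    labels = [
        w.label or f"scenario_{i + 1}" for i, w in enumerate(weight_scenarios)
    ]
    data = {
        lbl: [card.decision_score(w) for card in scorecards]
        for lbl, w in zip(labels, weight_scenarios)
    }
    df = pd.DataFrame(data, index=[c.alternative for c in scorecards])
    argmax: dict[str, str] = {}
    tied: list[str] = []
    for lbl in labels:
        col = df[lbl]
        best = col.max()
        winners = [a for a in df.index if best - col[a] <= tie_tol]
        argmax[lbl] = winners[0]
        if len(winners) > 1:
            tied.append(lbl)
    df.attrs["argmax"] = argmax
    df.attrs["ties"] = tied
    return df


@dataclass(frozen=True)
class SimplexSurface:
    """Decision scores over a grid of the weight simplex.

    ``x``/``y`` are the grid coordinates (weights of the two chosen
    criteria), ``scores[name]`` the per-alternative score at each point,
    ``argmax`` the winning alternative per point (``'tie'`` entries listed in
    ``ties`` by index).
    """

    x: np.ndarray
    y: np.ndarray
    scores: dict[str, np.ndarray]
    argmax: np.ndarray  # alternative name per grid point
    ties: np.ndarray  # indices of grid points whose top scores tie
    x_criterion: str
    y_criterion: str

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"x": self.x, "y": self.y})
        for name, s in self.scores.items():
            df[name] = s
        df["argmax"] = self.argmax
        return df


def continuous_sensitivity_surface(
    scorecards: Sequence[ScoreCard],
    x_criterion: str,
    y_criterion: str,
    grid_step: float = 0.01,
    tie_tol: float = 1e-12,
) -> SimplexSurface:
    """Per-alternative decision-score field over the weight simplex.

    At each grid point ``(x, y)`` with ``x + y ≤ 1`` the score of an
    alternative is ``S_x·x + S_y·y + S_z·(1 − x − y)`` where ``S_z`` is its
    score on the remaining criterion.  Points with ``x + y > 1`` are never
    evaluated.
    """
    if not 0 < grid_step <= 0.5:
        raise ValueError("grid_step must lie in (0, 0.5]")
    crit_names = list(scorecards[0].scores)
    rest = [c for c in crit_names if c not in (x_criterion, y_criterion)]
    if x_criterion == y_criterion or len(rest) != len(crit_names) - 2:
        raise KeyError(
            f"x/y criteria ({x_criterion!r}, {y_criterion!r}) must be two distinct "
            f"members of {crit_names}"
        )
    if len(rest) != 1:
        raise ValueError("the simplex surface requires exactly three criteria")
    z_criterion = rest[0]

    n = int(round(1.0 / grid_step))
    axis = np.arange(n + 1) * grid_step
    X, Y = np.meshgrid(axis, axis, indexing="ij")
    keep = X + Y <= 1.0 + 1e-12
    x = X[keep]
    y = Y[keep]
    z = 1.0 - x - y

    scores = {
        c.alternative: c.scores[x_criterion] * x
        + c.scores[y_criterion] * y
        + c.scores[z_criterion] * z
        for c in scorecards
    }
    names = list(scores)
    stacked = np.vstack([scores[n_] for n_ in names])
    best = stacked.max(axis=0)
    winner_idx = stacked.argmax(axis=0)
    argmax = np.array([names[i] for i in winner_idx], dtype=object)
    ties = np.flatnonzero((best - stacked <= tie_tol).sum(axis=0) > 1)
    return SimplexSurface(x, y, scores, argmax, ties, x_criterion, y_criterion)


@dataclass(frozen=True)
class DecisionBoundary:
    """Half-plane where alternative ``a`` beats ``b`` on the weight simplex:
    ``a`` is preferred iff ``coef_x·x + coef_y·y + constant > 0``."""

    a: str
    b: str
    coef_x: float
    coef_y: float
    constant: float
    degenerate: bool  # identical scorecards: scores equal everywhere

    def margin(self, point: WeightSimplexPoint) -> float:
        return self.coef_x * point.x + self.coef_y * point.y + self.constant

    def prefers_a(self, point: WeightSimplexPoint) -> bool:
        return self.margin(point) > 0

    def describe(self) -> str:
        if self.degenerate:
            return f"{self.a} and {self.b} score identically everywhere"
        return (
            f"{self.a} preferred over {self.b} iff "
            f"{self.coef_x:g}*x + {self.coef_y:g}*y + {self.constant:g} > 0"
        )


def decision_boundary(
    scorecards: Sequence[ScoreCard],
    alt_a: str,
    alt_b: str,
    x_criterion: str,
    y_criterion: str,
) -> DecisionBoundary:
    """Closed-form pairwise preference boundary on the weight simplex.

    The score difference DS_a − DS_b is affine in (x, y):
    ``(dS_x − dS_z)·x + (dS_y − dS_z)·y + dS_z`` with ``dS`` the per-criterion
    score differences; the boundary is its zero line.
    """
    if alt_a == alt_b:
        raise ValueError("decision boundary needs two distinct alternatives")
    cards = {c.alternative: c for c in scorecards}
    a, b = cards[alt_a], cards[alt_b]
    crit_names = list(a.scores)
    rest = [c for c in crit_names if c not in (x_criterion, y_criterion)]
    if len(rest) != 1:
        raise ValueError("the simplex boundary requires exactly three criteria")
    z_criterion = rest[0]
    d = {name: a.scores[name] - b.scores[name] for name in crit_names}
    coef_x = d[x_criterion] - d[z_criterion]
    coef_y = d[y_criterion] - d[z_criterion]
    constant = d[z_criterion]
    degenerate = coef_x == 0 and coef_y == 0 and constant == 0
    return DecisionBoundary(alt_a, alt_b, coef_x, coef_y, constant, degenerate)
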