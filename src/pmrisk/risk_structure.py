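"""Risk-factor uncertainty as cumulative probability curves over annual
increase rates, and their discretization into High/Medium/Low level
probabilities.

Each risk factor (e.g. population expansion, economic growth, temperature
increase) carries a subjective cumulative distribution function (CDF) of its
average annual increase rate, elicited from experts and model output.  A
level binning partitions the rate axis into labelled intervals (High /
Medium / Low); the probability of a level is the CDF mass falling in its
interval, evaluated with piecewise-linear interpolation between the curve's
knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CumulativeRateCurve",
    "LevelBinning",
    "FactorLevelDistribution",
    "level_probabilities",
]

PROB_TOL = 1e-9


class CurveValidationError(ValueError):
    """Raised when a cumulative rate curve violates its invariants."""


class RangeError(ValueError):
    """Raised when a binning interval lies outside a curve's rate range."""


@dataclass(frozen=True)
class CumulativeRateCurve:
    """Monotone CDF of a risk factor's annual increase rate.

    Parameters
    ----------
    factor_name
        Label of the risk factor the curve belongs to.
    rates
        Strictly increasing knot rates (fraction per year).
    cum_probs
        Non-decreasing cumulative probabilities at the knots; must start at
        0 and end at 1.
    band
        Optional ``(lower, upper)`` cumulative-probability envelopes at the
        same rates (an elicitation confidence band).  Carried for synthetic
        sampling only; point-estimate operations ignore it.
    """

    factor_name: str
    rates: tuple[float, ...]
    cum_probs: tuple[float, ...]
    band: Optional[tuple[tuple[float, ...], tuple[float, ...]]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", tuple(float(r) for r in self.rates))
        object.__setattr__(self, "cum_probs", tuple(float(p) for p in self.cum_probs))
        r = np.asarray(self.rates)
        p = np.asarray(self.cum_probs)
        if r.size != p.size or r.size < 2:
            raise CurveValidationError(
                f"{self.factor_name}: need >= 2 knots with matching rates/probabilities"
            )
        if not np.all(np.diff(r) > 0):
            raise CurveValidationError(f"{self.factor_name}: rates must be strictly increasing")
        if not np.all(np.diff(p) >= -PROB_TOL):
            raise CurveValidationError(
                f"{self.factor_name}: cumulative probabilities must be non-decreasing"
            )
        if np.any(p < -PROB_TOL) or np.any(p > 1 + PROB_TOL):
            raise CurveValidationError(f"{self.factor_name}: probabilities outside [0, 1]")
        if abs(p[0]) > PROB_TOL or abs(p[-1] - 1) > PROB_TOL:
            raise CurveValidationError(
                f"{self.factor_name}: curve must start at probability 0 and end at 1"
            )
        if self.band is not None:
            lower = np.asarray(self.band[0], dtype=float)
            upper = np.asarray(self.band[1], dtype=float)
            if lower.size != r.size or upper.size != r.size:
                raise CurveValidationError(
                    f"{self.factor_name}: band envelopes must share the curve's knot rates"
                )
            if np.any(lower > p + PROB_TOL) or np.any(upper < p - PROB_TOL):
                raise CurveValidationError(
                    f"{self.factor_name}: band must bracket the central curve pointwise"
                )
            object.__setattr__(
                self, "band", (tuple(map(float, lower)), tuple(map(float, upper)))
            )

    @property
    def rate_range(self) -> tuple[float, float]:
        return self.rates[0], self.rates[-1]

    def cdf(self, rate: float | np.ndarray) -> float | np.ndarray:
        """Cumulative probability at ``rate``, piecewise-linear between knots."""
        return np.interp(rate, self.rates, self.cum_probs)


@dataclass(frozen=True)
class LevelBinning:
    """Partition of a rate axis into labelled half-open intervals.

    Intervals are ``[lo, hi)`` with the topmost closed at its upper end, so
    touching boundaries are unambiguous (a rate exactly on a shared boundary
    belongs to the higher interval that starts there).
    """

    factor_name: str
    levels: tuple[str, ...]
    intervals: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        object.__setattr__(
            self,
            "intervals",
            {lvl: (float(lo), float(hi)) for lvl, (lo, hi) in self.intervals.items()},
        )
        if set(self.levels) != set(self.intervals):
            raise CurveValidationError(
                f"{self.factor_name}: levels and intervals must name the same set"
            )
        spans = sorted(self.intervals.values())
        for lo, hi in spans:
            if not hi > lo:
                raise CurveValidationError(f"{self.factor_name}: empty interval [{lo}, {hi})")
        for (_, hi_prev), (lo_next, _) in zip(spans, spans[1:]):
            if abs(hi_prev - lo_next) > PROB_TOL:
                raise CurveValidationError(
                    f"{self.factor_name}: intervals must be contiguous and disjoint"
                )

    @property
    def rate_range(self) -> tuple[float, float]:
        spans = sorted(self.intervals.values())
        return spans[0][0], spans[-1][1]


@dataclass(frozen=True)
class FactorLevelDistribution:
    """Probability of each increase level for one risk factor."""

    factor_name: str
    probabilities: dict[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "probabilities", {k: float(v) for k, v in self.probabilities.items()}
        )
        vals = np.asarray(list(self.probabilities.values()))
        if np.any(vals < -PROB_TOL) or np.any(vals > 1 + PROB_TOL):
            raise CurveValidationError(f"{self.factor_name}: level probability outside [0, 1]")
        if abs(vals.sum() - 1.0) > PROB_TOL:
            raise CurveValidationError(
                f"{self.factor_name}: level probabilities sum to {vals.sum():.12f}, not 1"
            )

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(self.probabilities)

    def __getitem__(self, level: str) -> float:
        return self.probabilities[level]


def level_probabilities(
    curve: CumulativeRateCurve, binning: LevelBinning
) -> FactorLevelDistribution:
    """Discretize a cumulative rate curve into level probabilities.

    ``P(level) = CDF(hi) - CDF(lo)`` for the level's interval ``[lo, hi)``,
    with piecewise-linear interpolation between the curve's knots.  Because
    the interpolated CDF is continuous, the half-open boundary convention
    carries no probability mass and the level probabilities sum to the CDF
    mass over the binned range.

    Raises
    ------
    RangeError
        If any binning interval extends beyond the curve's knot range.
    """
    lo_curve, hi_curve = curve.rate_range
    for level, (lo, hi) in binning.intervals.items():
        if lo < lo_curve - PROB_TOL or hi > hi_curve + PROB_TOL:
            raise RangeError(
                f"{binning.factor_name}/{level}: interval [{lo}, {hi}) outside "
                f"curve range [{lo_curve}, {hi_curve}]"
            )
    probs = {
        level: float(curve.cdf(hi) - curve.cdf(lo))
        for level, (lo, hi) in binning.intervals.items()
    }
    # Guard against floating-point drift; the analytic sum is CDF(top)-CDF(bottom).
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-6:
        raise CurveValidationError(
            f"{binning.factor_name}: binned probabilities sum to {total:.9f}; "
            "binning must cover the curve's full support"
        )
    probs = {k: v / total for k, v in probs.items()}
    return FactorLevelDistribution(curve.factor_name, probs)
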