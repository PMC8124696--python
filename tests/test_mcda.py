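"""Rank-bin MCDA scoring, weighted decision scores and weight sensitivity."""

import numpy as np
import pytest

from pmrisk.mcda import (
    BinDomainError,
    Criterion,
    CriterionWeights,
    ScoreCard,
    WeightSimplexPoint,
    continuous_sensitivity_surface,
    decision_boundary,
    discrete_sensitivity,
    rank_of,
    rank_to_score,
    weighted_score,
)
from pmrisk.synthetic_data import GeneratorConfig, random_mcda_problem

IE = Criterion("IE", bins=((100, 300, 1), (300, 500, 2), (500, 700, 3), (700, 900, 4)))
ID = Criterion("ID", categories={"Easy": 1, "Medium": 2, "Hard": 3, "Extremely hard": 4})
T = Criterion("T", bins=((0, 5, 1), (5, 10, 2), (10, 15, 3), (15, 20, 4)))


class TestRankOf:
    @pytest.mark.parametrize("value, rank", [(200, 1), (400, 2), (600, 3), (800, 4)])
    def test_numeric_bins(self, value, rank):
        assert rank_of(value, IE) == rank

    @pytest.mark.parametrize(
        "cat, rank", [("Easy", 1), ("Medium", 2), ("Hard", 3), ("Extremely hard", 4)]
    )
    def test_ordinal_categories(self, cat, rank):
        assert rank_of(cat, ID) == rank

    @pytest.mark.parametrize("boundary, rank", [(300, 2), (500, 3), (700, 4), (900, 4)])
    def test_touching_boundaries_belong_to_upper_bin(self, boundary, rank):
        """Half-open [lo, hi) bins with the top bin closed."""
        assert rank_of(boundary, IE) == rank

    def test_value_outside_all_bins_raises(self):
        with pytest.raises(BinDomainError):
            rank_of(50, IE)
        with pytest.raises(BinDomainError):
            rank_of("Impossible", ID)


class TestRankToScore:
    def test_best_rank_gets_top_score(self):
        assert rank_to_score(1, 4) == 4

    def test_worst_rank_gets_score_one(self):
        assert rank_to_score(4, 4) == 1

    @pytest.mark.parametrize("max_rank", range(1, 7))
    def test_reflection_oracle_exhaustive(self, max_rank):
        for rank in range(1, max_rank + 1):
            assert rank_to_score(rank, max_rank) == max_rank + 1 - rank

    def test_out_of_range_rank_rejected(self):
        with pytest.raises(ValueError):
            rank_to_score(0, 4)
        with pytest.raises(ValueError):
            rank_to_score(5, 4)


class TestWeightedScore:
    def test_ocean_going_vessels_decision_score(self):
        """Scores (4, 3, 4) under weights (0.6, 0.3, 0.1) give 3.7."""
        weights = CriterionWeights({"IE": 0.6, "ID": 0.3, "T": 0.1})
        assert weighted_score({"IE": 4, "ID": 3, "T": 4}, weights) == pytest.approx(3.7)

    def test_unit_weight_selects_that_criterion(self):
        weights = CriterionWeights({"IE": 1.0, "ID": 0.0, "T": 0.0})
        assert weighted_score({"IE": 2, "ID": 3, "T": 4}, weights) == 2.0

    def test_mismatched_criteria_raise(self):
        weights = CriterionWeights({"IE": 0.5, "ID": 0.5})
        with pytest.raises(KeyError):
            weighted_score({"IE": 1, "T": 2}, weights)

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(ValueError):
            CriterionWeights({"IE": 0.5, "ID": 0.4})

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_dot_product_oracle(self, seed):
        _, cards, weights = random_mcda_problem(GeneratorConfig(seed=seed))
        for card in cards:
            names = list(card.scores)
            oracle = float(
                np.dot([card.scores[n] for n in names], [weights[n] for n in names])
            )
            assert card.decision_score(weights) == pytest.approx(oracle, rel=1e-12)


class TestLaLbmaScorecards:
    def test_published_ranks_scores_and_decision_scores(self, case, scorecards):
        expected = {
            "ocean-going vessels": ({"investment efficiency": 4,
                                     "implementation difficulty": 3,
                                     "time to become effective": 4}, 3.7),
            "refineries": ({"investment efficiency": 2,
                            "implementation difficulty": 2,
                            "time to become effective": 3}, 2.1),
            "electricity-generating units": ({"investment efficiency": 1,
                                              "implementation difficulty": 3,
                                              "time to become effective": 2}, 1.7),
        }
        for card in scorecards:
            scores, ds = expected[card.alternative]
            assert card.scores == scores
            assert card.decision_score(case.weights) == pytest.approx(ds, abs=1e-12)


class TestDiscreteSensitivity:
    def test_ocean_going_vessels_wins_all_five_scenarios(self, case, scorecards):
        df = discrete_sensitivity(scorecards, case.weight_scenarios)
        assert set(df.attrs["argmax"].values()) == {"ocean-going vessels"}
        assert df.attrs["ties"] == []

    def test_single_scenario_reduces_to_weighted_score(self, case, scorecards):
        df = discrete_sensitivity(scorecards, [case.weights])
        col = df.iloc[:, 0]
        for card in scorecards:
            assert col[card.alternative] == pytest.approx(card.decision_score(case.weights))

    def test_empty_scenarios_rejected(self, scorecards):
        with pytest.raises(ValueError):
            discrete_sensitivity(scorecards, [])

    @pytest.mark.parametrize("seed", range(20))
    def test_every_cell_equals_weighted_score_oracle(self, seed):
        _, cards, _ = random_mcda_problem(GeneratorConfig(seed=seed))
        rng = np.random.default_rng(seed + 1)
        names = list(cards[0].scores)
        scenarios = [
            CriterionWeights(dict(zip(names, rng.dirichlet(np.ones(len(names))))))
            for _ in range(4)
        ]
        df = discrete_sensitivity(cards, scenarios)
        for j, w in enumerate(scenarios):
            for card in cards:
                assert df.iloc[:, j][card.alternative] == pytest.approx(
                    card.decision_score(w)
                )


class TestContinuousSurface:
    def test_ocean_going_vessels_is_argmax_everywhere(self, case, scorecards):
        surface = continuous_sensitivity_surface(
            scorecards, case.x_criterion, case.y_criterion, 0.01
        )
        assert set(surface.argmax) == {"ocean-going vessels"}
        # strict dominance everywhere except the single vertex (x, y) = (0, 1),
        # where ocean-going vessels and electricity-generating units both
        # carry an implementation-difficulty score of 3
        tie_pts = list(zip(surface.x[surface.ties], surface.y[surface.ties]))
        assert tie_pts in ([], [(0.0, 1.0)])

    def test_simplex_constraint_respected(self, case, scorecards):
        surface = continuous_sensitivity_surface(
            scorecards, case.x_criterion, case.y_criterion, 0.05
        )
        assert np.all(surface.x + surface.y <= 1 + 1e-12)
        # triangular grid with step 0.05: 21 + 20 + ... + 1 points
        assert surface.x.size == 21 * 22 // 2

    def test_base_weights_point_reproduces_decision_scores(self, case, scorecards):
        surface = continuous_sensitivity_surface(
            scorecards, case.x_criterion, case.y_criterion, 0.01
        )
        at = (np.abs(surface.x - 0.6) < 1e-9) & (np.abs(surface.y - 0.3) < 1e-9)
        assert at.sum() == 1
        expected = {"ocean-going vessels": 3.7, "refineries": 2.1,
                    "electricity-generating units": 1.7}
        for name, s in expected.items():
            assert surface.scores[name][at][0] == pytest.approx(s, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_surface_is_affine_in_the_weights(self, seed):
        """Midpoint of any two grid points carries the mean of their scores."""
        _, cards, _ = random_mcda_problem(GeneratorConfig(seed=seed))
        names = list(cards[0].scores)
        surface = continuous_sensitivity_surface(cards, names[0], names[1], 0.25)
        for alt, s in surface.scores.items():
            card = next(c for c in cards if c.alternative == alt)
            mid_x = (surface.x[0] + surface.x[-1]) / 2
            mid_y = (surface.y[0] + surface.y[-1]) / 2
            mid_score = (
                card.scores[names[0]] * mid_x
                + card.scores[names[1]] * mid_y
                + card.scores[names[2]] * (1 - mid_x - mid_y)
            )
            assert mid_score == pytest.approx((s[0] + s[-1]) / 2, rel=1e-12)

    def test_grid_argmax_consistent_with_vertex_evaluation(self, case, scorecards):
        """DS is affine in the weights, so the simplex max is attained at a
        vertex; the grid winner must win at least one vertex."""
        surface = continuous_sensitivity_surface(
            scorecards, case.x_criterion, case.y_criterion, 0.5
        )
        names = [c.alternative for c in scorecards]
        crit = list(scorecards[0].scores)
        vertex_winners = set()
        for w in (
            {crit[0]: 1.0, crit[1]: 0.0, crit[2]: 0.0},
            {crit[0]: 0.0, crit[1]: 1.0, crit[2]: 0.0},
            {crit[0]: 0.0, crit[1]: 0.0, crit[2]: 1.0},
        ):
            cw = CriterionWeights(w)
            scores = {c.alternative: c.decision_score(cw) for c in scorecards}
            vertex_winners.add(max(scores, key=scores.get))
        assert set(surface.argmax) <= vertex_winners

    def test_invalid_grid_step_rejected(self, scorecards, case):
        with pytest.raises(ValueError):
            continuous_sensitivity_surface(scorecards, case.x_criterion, case.y_criterion, 0.0)


class TestDecisionBoundary:
    def test_refineries_vs_electricity_boundary_is_y_half(self, case, scorecards):
        """DS_refineries − DS_electricity = 1 − 2y: refineries preferred iff
        the implementation-difficulty weight y < 0.5."""
        bd = decision_boundary(
            scorecards, "refineries", "electricity-generating units",
            case.x_criterion, case.y_criterion,
        )
        assert bd.coef_x == 0.0
        assert bd.coef_y == pytest.approx(-2.0)
        assert bd.constant == pytest.approx(1.0)
        assert bd.prefers_a(WeightSimplexPoint(0.3, 0.49))
        assert not bd.prefers_a(WeightSimplexPoint(0.3, 0.51))
        assert bd.margin(WeightSimplexPoint(0.3, 0.5)) == pytest.approx(0.0)

    def test_ocean_vs_refineries_has_no_boundary_inside_simplex(self, case, scorecards):
        """DS_ocean − DS_refineries = 1 + x > 0 on the whole simplex."""
        bd = decision_boundary(
            scorecards, "ocean-going vessels", "refineries",
            case.x_criterion, case.y_criterion,
        )
        assert (bd.coef_x, bd.coef_y, bd.constant) == (1.0, 0.0, 1.0)
        xs = np.linspace(0, 1, 11)
        for x in xs:
            for y in np.linspace(0, 1 - x, 11):
                assert bd.margin(WeightSimplexPoint(x, y)) > 0

    def test_boundary_matches_grid_argmax(self, case, scorecards):
        bd = decision_boundary(
            scorecards, "refineries", "electricity-generating units",
            case.x_criterion, case.y_criterion,
        )
        pair = [c for c in scorecards if c.alternative != "ocean-going vessels"]
        surface = continuous_sensitivity_surface(
            pair, case.x_criterion, case.y_criterion, 0.01
        )
        for x, y, winner in zip(surface.x, surface.y, surface.argmax):
            m = bd.margin(WeightSimplexPoint(x, y))
            if abs(m) < 1e-12:
                continue  # boundary cells are ties
            assert (winner == "refineries") == (m > 0)
        # boundary cells flagged as ties exactly at y = 0.5
        tie_y = surface.y[surface.ties]
        assert np.allclose(tie_y, 0.5)

    def test_identical_scorecards_are_degenerate(self, case, scorecards):
        twin = ScoreCard("twin", scorecards[0].raw, scorecards[0].ranks, scorecards[0].scores)
        bd = decision_boundary(
            [scorecards[0], twin], scorecards[0].alternative, "twin",
            case.x_criterion, case.y_criterion,
        )
        assert bd.degenerate

    def test_same_alternative_rejected(self, case, scorecards):
        with pytest.raises(ValueError):
            decision_boundary(scorecards, "refineries", "refineries",
                              case.x_criterion, case.y_criterion)
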