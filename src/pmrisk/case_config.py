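"""Case-configuration schema, validation, pipeline driver and report writers.

A case file (YAML or JSON) has three sections:

``risk``
    level binnings and cumulative rate curves per risk factor, a consequence
    distribution, a conditional risk table (both directions), and optionally
    an explicit event tree.
``decision``
    the baseline concentration standard, increase scenarios, mitigation
    alternatives, air volume V and the risk tolerances R to evaluate.
``mcda``
    criteria with rank bins, raw assessments per alternative, baseline
    weights, discrete weight scenarios, and the simplex-grid settings.

``load_case`` validates the parsed document and raises with a list of
JSON-pointer-style paths on violation; ``run_pipeline`` executes every stage
(risk rating → critical factor → EMV/EU → MCDA → sensitivity) and returns a
deterministic, JSON-serializable report bundle.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import decision_value as dv
from . import event_tree as et
from . import mcda as mc
from . import risk_structure as rs

__all__ = [
    "CaseConfiguration",
    "CaseValidationError",
    "load_case",
    "save_case",
    "validate_case",
    "run_pipeline",
    "PipelineReport",
]

logger = logging.getLogger(__name__)


class CaseValidationError(ValueError):
    """Configuration violates the case schema; ``violations`` lists paths."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__(
            "invalid case configuration:\n" + "\n".join(f"  - {v}" for v in violations)
        )


# ---------------------------------------------------------------------------
# schema validation (plain-dict level, before object construction)

def _is_prob(v: Any) -> bool:
    return isinstance(v, (int, float)) and 0.0 <= v <= 1.0


def validate_case(doc: Any) -> list[str]:
    """Check a parsed case document against the schema.

    Returns a list of violations as ``section.path: message`` strings; empty
    when the document is valid.  Structural errors short-circuit deeper
    checks along the same path.
    """
    v: list[str] = []
    if not isinstance(doc, dict):
        return ["/: document must be a mapping"]

    risk = doc.get("risk")
    if not isinstance(risk, dict):
        v.append("risk: missing or not a mapping")
    else:
        for i, b in enumerate(risk.get("binnings", []) or []):
            p = f"risk.binnings[{i}]"
            if "factor" not in b:
                v.append(f"{p}.factor: missing")
            for lvl, span in (b.get("intervals") or {}).items():
                if not (isinstance(span, (list, tuple)) and len(span) == 2 and span[1] > span[0]):
                    v.append(f"{p}.intervals.{lvl}: must be [lo, hi] with hi > lo")
        for i, c in enumerate(risk.get("curves", []) or []):
            p = f"risk.curves[{i}]"
            knots = c.get("knots")
            if not isinstance(knots, list) or len(knots) < 2:
                v.append(f"{p}.knots: need >= 2 [rate, probability] pairs")
                continue
            for j, kn in enumerate(knots):
                if not (isinstance(kn, (list, tuple)) and len(kn) == 2 and _is_prob(kn[1])):
                    v.append(f"{p}.knots[{j}]: must be [rate, probability in [0,1]]")
        cd = risk.get("consequence_distribution")
        if isinstance(cd, dict):
            for cat, p_ in (cd.get("probabilities") or {}).items():
                if not _is_prob(p_):
                    v.append(
                        f"risk.consequence_distribution.probabilities.{cat}: "
                        f"{p_!r} is not a probability in [0, 1]"
                    )
        crt = risk.get("conditional_risk_table")
        if isinstance(crt, dict):
            for fac, levels in (crt.get("forward") or {}).items():
                for lvl, p_ in (levels or {}).items():
                    if not _is_prob(p_):
                        v.append(
                            f"risk.conditional_risk_table.forward.{fac}.{lvl}: "
                            f"{p_!r} is not a probability in [0, 1]"
                        )
            for fac, p_ in (crt.get("inverse") or {}).items():
                if not _is_prob(p_):
                    v.append(
                        f"risk.conditional_risk_table.inverse.{fac}: "
                        f"{p_!r} is not a probability in [0, 1]"
                    )

    dec = doc.get("decision")
    if not isinstance(dec, dict):
        v.append("decision: missing or not a mapping")
    else:
        if not (isinstance(dec.get("baseline_standard"), (int, float)) and dec["baseline_standard"] > 0):
            v.append("decision.baseline_standard: must be a positive number")
        if "volume" in dec and not (isinstance(dec["volume"], (int, float)) and dec["volume"] > 0):
            v.append("decision.volume: must be a positive number")
        scen_labels = []
        for i, s in enumerate(dec.get("scenarios", []) or []):
            p = f"decision.scenarios[{i}]"
            if "label" not in s:
                v.append(f"{p}.label: missing")
            else:
                scen_labels.append(s["label"])
            if not (isinstance(s.get("increase_rate"), (int, float)) and s["increase_rate"] > 0):
                v.append(f"{p}.increase_rate: must be a positive number")
        for i, a in enumerate(dec.get("alternatives", []) or []):
            p = f"decision.alternatives[{i}]"
            if "name" not in a:
                v.append(f"{p}.name: missing")
            if not (isinstance(a.get("dollars_per_ton"), (int, float)) and a["dollars_per_ton"] > 0):
                v.append(f"{p}.dollars_per_ton: must be a positive number")
            for block in ("scenario_probability", "success_probability"):
                probs = a.get(block)
                if not isinstance(probs, dict):
                    v.append(f"{p}.{block}: missing or not a mapping")
                    continue
                for lbl, p_ in probs.items():
                    if not _is_prob(p_):
                        v.append(f"{p}.{block}.{lbl}: {p_!r} is not a probability in [0, 1]")
                missing = [l for l in scen_labels if l not in probs]
                if missing:
                    v.append(f"{p}.{block}: missing scenarios {missing}")
            sp = a.get("scenario_probability")
            if isinstance(sp, dict) and all(_is_prob(x) for x in sp.values()):
                total = sum(sp.values())
                if abs(total - 1.0) > 1e-9:
                    v.append(f"{p}.scenario_probability: sums to {total}, not 1")

    mcda = doc.get("mcda")
    if not isinstance(mcda, dict):
        v.append("mcda: missing or not a mapping")
    else:
        crit_names = []
        for i, c in enumerate(mcda.get("criteria", []) or []):
            p = f"mcda.criteria[{i}]"
            if "name" not in c:
                v.append(f"{p}.name: missing")
            else:
                crit_names.append(c["name"])
            if ("bins" in c) == ("categories" in c):
                v.append(f"{p}: declare exactly one of bins / categories")
        for alt, raw in (mcda.get("assessments") or {}).items():
            missing = [c for c in crit_names if c not in (raw or {})]
            if missing:
                v.append(f"mcda.assessments.{alt}: missing criteria {missing}")
        for wname, wblock in [("weights", mcda.get("weights"))] + [
            (f"weight_scenarios[{i}].weights", (ws or {}).get("weights"))
            for i, ws in enumerate(mcda.get("weight_scenarios", []) or [])
        ]:
            if not isinstance(wblock, dict):
                v.append(f"mcda.{wname}: missing or not a mapping")
                continue
            bad = {k: w for k, w in wblock.items() if not _is_prob(w)}
            for k, w in bad.items():
                v.append(f"mcda.{wname}.{k}: {w!r} is not a weight in [0, 1]")
            if not bad and abs(sum(wblock.values()) - 1.0) > 1e-9:
                v.append(f"mcda.{wname}: weights sum to {sum(wblock.values())}, not 1")
        gs = mcda.get("grid_step", 0.01)
        if not (isinstance(gs, (int, float)) and 0 < gs <= 0.5):
            v.append("mcda.grid_step: must lie in (0, 0.5]")
    return v


# ---------------------------------------------------------------------------
# typed configuration

@dataclass
class CaseConfiguration:
    """A validated case: typed objects for every pipeline stage plus the raw
    document (for provenance labels and round-tripping)."""

    curves: dict[str, rs.CumulativeRateCurve]
    binnings: dict[str, rs.LevelBinning]
    consequence_distribution: et.ConsequenceDistribution
    renormalize_consequence: bool
    conditional_risk_table: et.ConditionalRiskTable
    tree: Optional[et.EventTree]
    scenarios: list[dv.IncreaseScenario]
    alternatives: list[dv.MitigationAlternative]
    volume: float
    risk_tolerances: list[float]
    criteria: list[mc.Criterion]
    assessments: dict[str, dict[str, Any]]
    weights: mc.CriterionWeights
    weight_scenarios: list[mc.CriterionWeights]
    grid_step: float
    x_criterion: str
    y_criterion: str
    raw_doc: dict = field(repr=False, default_factory=dict)

    @classmethod
    def from_dict(cls, doc: dict) -> "CaseConfiguration":
        violations = validate_case(doc)
        if violations:
            raise CaseValidationError(violations)

        risk = doc["risk"]
        binnings = {
            b["factor"]: rs.LevelBinning(
                b["factor"],
                tuple(b["levels"]),
                {lvl: tuple(span) for lvl, span in b["intervals"].items()},
            )
            for b in risk.get("binnings", [])
        }
        curves = {
            c["factor"]: rs.CumulativeRateCurve(
                c["factor"],
                tuple(k[0] for k in c["knots"]),
                tuple(k[1] for k in c["knots"]),
            )
            for c in risk.get("curves", [])
        }
        cd_block = risk["consequence_distribution"]
        consequence = et.ConsequenceDistribution(dict(cd_block["probabilities"]))
        crt_block = risk["conditional_risk_table"]
        forward = {
            (fac, lvl): {"High": p}
            for fac, levels in crt_block["forward"].items()
            for lvl, p in levels.items()
        }
        inverse = {
            (fac, "High"): {"High": p} for fac, p in crt_block["inverse"].items()
        }
        table = et.ConditionalRiskTable(
            forward, inverse, tuple(crt_block["forward"])
        )

        tree = None
        tree_block = risk.get("reconstructed_tree") or risk.get("tree")
        if tree_block:
            factors = tuple(
                rs.FactorLevelDistribution(f["factor"], dict(f["probabilities"]))
                for f in tree_block["factors"]
            )
            cmap = {
                tuple(entry[:-1]): entry[-1]
                for entry in tree_block["consequence_map"]
            }
            tree = et.EventTree(factors, cmap)

        dec = doc["decision"]
        standard = float(dec["baseline_standard"])
        scenarios = [
            dv.IncreaseScenario(s["label"], float(s["increase_rate"]), standard)
            for s in dec["scenarios"]
        ]
        alternatives = []
        for a in dec["alternatives"]:
            alternatives.append(
                dv.MitigationAlternative(
                    a["name"],
                    float(a["dollars_per_ton"]),
                    dict(a["scenario_probability"]),
                    dict(a["success_probability"]),
                )
            )
            if "elicited_scenario_probability" in a:
                logger.warning(
                    "%s: using the published valuation-table scenario probabilities "
                    "%s; an earlier elicited vector %s is recorded in the case file "
                    "and is inconsistent with the published EMV",
                    a["name"],
                    a["scenario_probability"],
                    a["elicited_scenario_probability"],
                )

        mcda = doc["mcda"]
        criteria = []
        for c in mcda["criteria"]:
            if "bins" in c:
                criteria.append(
                    mc.Criterion(
                        c["name"],
                        bins=tuple(tuple(b) for b in c["bins"]),
                        unit=c.get("unit", ""),
                    )
                )
            else:
                criteria.append(mc.Criterion(c["name"], categories=dict(c["categories"])))
        weight_scenarios = [
            mc.CriterionWeights(dict(ws["weights"]), ws.get("label", ""))
            for ws in mcda.get("weight_scenarios", [])
        ]

        return cls(
            curves=curves,
            binnings=binnings,
            consequence_distribution=consequence,
            renormalize_consequence=bool(cd_block.get("renormalize", False)),
            conditional_risk_table=table,
            tree=tree,
            scenarios=scenarios,
            alternatives=alternatives,
            volume=float(dec.get("volume", 1.0)),
            risk_tolerances=[float(r) for r in dec.get("risk_tolerances", [100.0])],
            criteria=criteria,
            assessments={k: dict(v) for k, v in mcda["assessments"].items()},
            weights=mc.CriterionWeights(dict(mcda["weights"])),
            weight_scenarios=weight_scenarios,
            grid_step=float(mcda.get("grid_step", 0.01)),
            x_criterion=mcda.get("x_criterion", criteria[0].name),
            y_criterion=mcda.get("y_criterion", criteria[1].name),
            raw_doc=doc,
        )

    def to_dict(self) -> dict:
        return self.raw_doc


def load_case(path: str | Path) -> CaseConfiguration:
    """Parse and validate a YAML/JSON case file."""
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return CaseConfiguration.from_dict(doc)


def save_case(case: CaseConfiguration, path: str | Path) -> None:
    """Write the case document back out (YAML unless the suffix is .json)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(case.raw_doc, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(case.raw_doc, sort_keys=False))


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class PipelineReport:
    """Deterministic bundle of every stage's outputs."""

    level_distributions: dict[str, dict[str, float]]
    consequence_distribution: dict[str, float]
    consequence_total: float
    conditional_risk_table: dict[str, dict[str, float]]
    critical_factor: str
    critical_factor_ties: list[str]
    valuations: dict[str, dict]  # per alternative
    emv_ranking: list[str]
    eu_rankings: dict[str, list[str]]  # per risk tolerance
    emv_ratios: dict[str, float]
    scorecards: dict[str, dict]
    decision_scores: dict[str, float]
    mcda_ranking: list[str]
    discrete_sensitivity: dict[str, dict[str, float]]
    discrete_argmax: dict[str, str]
    surface_argmax_share: dict[str, float]
    surface_grid_points: int
    boundaries: list[dict]

    def to_json(self, **kwargs: Any) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.__dict__, **kwargs)

    def write_csv(self, outdir: str | Path) -> list[Path]:
        """Write the tabular stage outputs as CSV files; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        frames = {
            "level_distributions.csv": pd.DataFrame(
                [
                    {"factor": f, "level": lvl, "probability": p}
                    for f, dist in self.level_distributions.items()
                    for lvl, p in dist.items()
                ]
            ),
            "valuations.csv": pd.DataFrame(
                [
                    {"alternative": name, **{k: v for k, v in val.items() if not isinstance(v, dict)}}
                    for name, val in self.valuations.items()
                ]
            ),
            "decision_scores.csv": pd.DataFrame(
                [{"alternative": a, "decision_score": s} for a, s in self.decision_scores.items()]
            ),
            "discrete_sensitivity.csv": pd.DataFrame(self.discrete_sensitivity),
        }
        for name, df in frames.items():
            p = outdir / name
            df.to_csv(p, index=False)
            written.append(p)
        return written


def run_pipeline(case: CaseConfiguration) -> PipelineReport:
    """Execute every stage of the risk-and-decision analysis.

    Stages: level probabilities from the curves, consequence distribution and
    risk rating, critical-factor selection, EMV/EU valuation and rankings at
    each risk tolerance, MCDA scoring, discrete weight-scenario sensitivity,
    the continuous simplex surface, and pairwise decision boundaries.
    """
    # --- risk structure
    try:
        level_dists = {
            name: rs.level_probabilities(curve, case.binnings[name]).probabilities
            for name, curve in case.curves.items()
            if name in case.binnings
        }
    except Exception as exc:  # pragma: no cover - stage naming only
        raise RuntimeError(f"risk_structure stage failed: {exc}") from exc

    # --- risk rating
    try:
        cd = case.consequence_distribution
        if case.renormalize_consequence:
            cd = cd.renormalized()
        critical, ties = et.select_critical_factor(case.conditional_risk_table)
        inverse_high = {
            f: case.conditional_risk_table.inverse[(f, "High")]["High"]
            for f in case.conditional_risk_table.factor_order
            if (f, "High") in case.conditional_risk_table.inverse
        }
    except Exception as exc:
        raise RuntimeError(f"event_tree stage failed: {exc}") from exc

    # --- valuation
    try:
        base_r = case.risk_tolerances[0]
        valuations = {}
        by_r: dict[float, list[dv.ValuationResult]] = {}
        for r in case.risk_tolerances:
            by_r[r] = [
                dv.valuate(alt, case.scenarios, case.volume, r)
                for alt in case.alternatives
            ]
        for val in by_r[base_r]:
            valuations[val.name] = {
                "emv": val.emv,
                "monetary_values": val.monetary_values,
                "eu_by_risk_tolerance": {
                    str(r): next(v.eu for v in by_r[r] if v.name == val.name)
                    for r in case.risk_tolerances
                },
            }
        emv_ranking, _ = dv.rank_alternatives(by_r[base_r], "emv")
        eu_rankings = {
            str(r): dv.rank_alternatives(by_r[r], "eu")[0] for r in case.risk_tolerances
        }
        top = emv_ranking[0]
        emv_ratios = {
            f"{top} / {other}": dv.emv_ratio(top, other, by_r[base_r])[0]
            for other in emv_ranking[1:]
        }
    except Exception as exc:
        raise RuntimeError(f"decision_value stage failed: {exc}") from exc

    # --- MCDA
    try:
        cards = [
            mc.ScoreCard.from_raw(alt, case.assessments[alt], case.criteria)
            for alt in case.assessments
        ]
        scores = {c.alternative: c.decision_score(case.weights) for c in cards}
        mcda_ranking = sorted(scores, key=scores.get, reverse=True)
        sens = mc.discrete_sensitivity(cards, case.weight_scenarios or [case.weights])
        surface = mc.continuous_sensitivity_surface(
            cards, case.x_criterion, case.y_criterion, case.grid_step
        )
        names, counts = np.unique(surface.argmax, return_counts=True)
        share = {str(n): float(c) / surface.argmax.size for n, c in zip(names, counts)}
        boundaries = []
        alt_names = [c.alternative for c in cards]
        for i, a in enumerate(alt_names):
            for b in alt_names[i + 1:]:
                bd = mc.decision_boundary(cards, a, b, case.x_criterion, case.y_criterion)
                boundaries.append(
                    {
                        "a": bd.a,
                        "b": bd.b,
                        "coef_x": bd.coef_x,
                        "coef_y": bd.coef_y,
                        "constant": bd.constant,
                        "degenerate": bd.degenerate,
                        "description": bd.describe(),
                    }
                )
    except Exception as exc:
        raise RuntimeError(f"mcda stage failed: {exc}") from exc

    return PipelineReport(
        level_distributions=level_dists,
        consequence_distribution=dict(cd.probabilities),
        consequence_total=cd.total,
        conditional_risk_table={
            "P(factor=High | consequence=High)": inverse_high,
        },
        critical_factor=critical,
        critical_factor_ties=ties,
        valuations=valuations,
        emv_ranking=emv_ranking,
        eu_rankings=eu_rankings,
        emv_ratios=emv_ratios,
        scorecards={
            c.alternative: {"ranks": c.ranks, "scores": c.scores} for c in cards
        },
        decision_scores=scores,
        mcda_ranking=mcda_ranking,
        discrete_sensitivity={
            col: {a: float(sens.loc[a, col]) for a in sens.index} for col in sens.columns
        },
        discrete_argmax=dict(sens.attrs["argmax"]),
        surface_argmax_share=share,
        surface_grid_points=int(surface.argmax.size),
        boundaries=boundaries,
    )
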