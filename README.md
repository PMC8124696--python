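# pmrisk

Risk and decision analysis for future fine-particulate (PM2.5) concentration
increase, packaged as a reusable pipeline with the Los Angeles–Long Beach
Metro Area (LA-LBMA) case study built in.

## Who this is for

Environmental-health analysts and decision scientists who need to (a) turn
expert beliefs about risk factors (population expansion, economic growth,
temperature increase) into a probabilistic rating of what drives a future
air-quality exceedance, and (b) compare mitigation investments (industrial
sectors whose PM2.5 emissions can be reduced) under both monetary and
multi-criteria preference models.

## The model

**Risk analysis.** Each risk factor carries a cumulative probability curve
F(r) over its annual increase rate r, discretized by level bins into
P(level) = F(hi) − F(lo) for High/Medium/Low. Assuming independent factors,
an event tree enumerates every joint level tuple; each path's probability is
the product of its branch probabilities, and paths map to a consequence
category (High/Medium/Low PM2.5 increase). Risk rating inverts the forward
conditionals with Bayes' rule,

    P(factor = High | consequence = High)
      = P(consequence = High | factor = High) · P(factor = High) / P(consequence = High),

and the *critical factor* is the argmax of that inverse conditional.

**Valuation.** A scenario needing a reduction of Δc µg/m³ over air volume V
m³ requires removing Δc·V·10⁻¹² metric tons of PM2.5. With benefit value d
$/ton and success probability q, a sector's scenario monetary value is
MV = q·d·Δc·V·10⁻¹², and

    EMV = Σᵢ Pᵢ·MVᵢ               (expected monetary value)
    EU  = Σᵢ Pᵢ·(1 − e^(−MVᵢ/R))  (exponential expected utility, risk tolerance R)

**MCDA.** Alternatives are assessed on criteria via ordered rank bins
(rank 1 = best), reflected into scores S = max_rank + 1 − rank, and combined
as DS = Σⱼ CWⱼ·Sⱼ. Because DS is affine in the weights, sensitivity over the
weight simplex {(x, y): x, y ≥ 0, x + y ≤ 1} reduces to half-plane decision
boundaries, which `decision_boundary` extracts in closed form.

## Worked example

```python
>>> import pmrisk
>>> case = pmrisk.la_lbma_case()
>>> report = pmrisk.run_pipeline(case)
>>> report.critical_factor
'economic growth'
>>> {name: f"{v['emv']:.3g}" for name, v in report.valuations.items()}
{'ocean-going vessels': '7.64e-08', 'refineries': '4.86e-07',
 'electricity-generating units': '1.37e-07'}
>>> report.emv_ratios
{'refineries / electricity-generating units': 3.542295081967213,
 'refineries / ocean-going vessels': 6.3649788698097485}
>>> report.decision_scores
{'ocean-going vessels': 3.6999999999999997, 'refineries': 2.0999999999999996,
 'electricity-generating units': 1.7}
>>> report.surface_argmax_share
{'ocean-going vessels': 1.0}
```

Reading these numbers: economic growth is the factor most likely to be High
given a High PM2.5 increase, so it anchors the decision context. Per unit
air volume, investing in refineries carries the largest expected monetary
value (4.86×10⁻⁷ V USD) — about 3.5× the electricity-generating units sector
and 6.4× ocean-going vessels — and stays preferred under the exponential
utility at every risk tolerance evaluated. But once investment efficiency,
implementation difficulty and time-to-effect are weighed together, ocean-going
vessels score highest (3.7 vs 2.1 and 1.7) and win at **every** point of the
weight simplex; refineries beat electricity-generating units exactly when the
implementation-difficulty weight y < 0.5.

The same pipeline runs from the shell:

```
pmrisk emv
pmrisk eu --risk-tolerance 5
pmrisk sensitivity --mode continuous --grid-step 0.01
pmrisk report --out report.json
```

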