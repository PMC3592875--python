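# markovcea

A Markov cohort cost-effectiveness model comparing first-line **erlotinib
monotherapy** with **carboplatin–gemcitabine (CG) chemotherapy** in advanced
EGFR mutation-positive non-small-cell lung cancer, from the perspective of the
Chinese health-care system (costs in 2010 USD). It is written for health
economists and methods researchers who want a transparent, scriptable and fully
tested re-implementation of a trial-based three-state decision model: survival
calibration, cohort trace, cost/QALY accounting, ICERs, tornado diagrams,
probabilistic sensitivity analysis and cost-effectiveness acceptability curves.

## The model

Three mutually exclusive health states — progression-free survival (PFS),
disease progression (DP) and death — evaluated in 3-week cycles over a 10-year
horizon (174 cycles), with costs and effects discounted at 3% per year.

- **PFS exit.** Each arm's PFS curve is Weibull, S(t) = exp(−(t/λ)^γ), by
  default exponential (γ = 1) and anchored to that arm's trial median
  (13.1 months erlotinib, 4.6 months CG): λ = m/ln 2. Per-cycle transition
  probabilities are p_k = 1 − S(k·u)/S((k−1)·u) for cycle length u.
- **Post-progression mortality.** The trial reported no overall-survival
  curve, so the constant per-cycle DP→death probability of each arm is
  back-calibrated (bisection) so that the discounted person-years spent in DP
  match the published values (1.23 years erlotinib, 3.65 years CG).
- **Costs.** CG pays 1599.41/cycle for 4 chemotherapy cycles plus blood tests
  (10.59), then best supportive care (1415.4) while progression-free, plus an
  expected one-off adverse-event management charge
  (0.42×461.5 + 0.40×3395 + 0.13×531.7 = 1620.951). Erlotinib pays
  1971.1/cycle plus tests (3.53) for 7 cycles; from cycle 8 the drug is
  donated and costs nothing. Both arms pay 1209.96 per DP cycle.
- **Effects.** QALYs weight discounted state person-time by utilities 0.65
  (PFS, erlotinib), 0.56 (PFS, CG) and 0.47 (DP).
- **Decision statistics.** ICER = ΔCost/ΔEffect (reported CG-minus-erlotinib),
  net monetary benefit NMB = λ·QALY − Cost at the willingness-to-pay threshold
  λ = $13,527/QALY (3× China's per-capita GDP), one-way sensitivity over the
  published parameter table, and a Monte-Carlo PSA whose distributions are
  moment-matched to each parameter's range (read as a 95% interval).

## Worked example

```python
from markovcea import CostEffectivenessModel

res = CostEffectivenessModel().fit()   # published base case
print(res.summary())
```

```
Markov cohort cost-effectiveness results (discounted, 2010 USD)
================================================================
             LY  QALY      Cost  median PFS (mo)
strategy
erlotinib  2.70  1.54  37852.38            13.10
cg         4.17  2.00  91736.11             4.61
----------------------------------------------------------------
Calibrated per-cycle DP death probability: erlotinib 0.04273, cg 0.01227
Incremental (CG minus erlotinib): dCost 53883.73, dQALY 0.47, dLY 1.46
ICER: 115151.28 USD/QALY, 36869.00 USD/LY
At WTP 13527 USD/QALY the preferred strategy is erlotinib (NMB erlotinib -17068.64, cg -64622.56)
```

The model medians (13.10 and 4.61 months) reproduce the trial medians to
within one 0.69-month cycle, and the calibrated DP death probabilities show
the expected ordering — progression on erlotinib happens later but is followed
by shorter post-progression survival. Chemotherapy accrues more (discounted)
life-years and QALYs but at a far higher lifetime cost, and at the $13,527/QALY
threshold erlotinib has the higher net monetary benefit: CG is not
cost-effective. Under the exponential PFS calibration the deterministic ICER is
higher than the one obtained from the original model's (unpublished)
Weibull shapes, but every decision-relevant conclusion is unchanged; see
`docs/methods.md`.

Uncertainty analyses hang off the results object:

```python
df = res.tornado()                     # one-way ICER spreads, widest first
psa = res.run_psa(n_iter=1000, seed=2013)
psa.quadrant_proportions()             # {'NE': 0.952, 'NW': 0.048, ...}
psa.prob_cg_cost_effective(13527.0)    # 0.0
psa.plot_ceac()
```

The same analyses are available from a shell:

```bash
markovcea base-case
markovcea tornado
markovcea psa -n 1000 --seed 2013
markovcea calibrate
markovcea simulate-trial --seed 1 --n-per-arm 500
```

Every command accepts `--config` (a flat YAML file overriding any published
default — see `markovcea.params`) and writes CSV/JSON outputs plus a run
manifest under `--output-dir`.

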