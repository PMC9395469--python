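# lungcea

Markov cohort cost-effectiveness analysis of lung-cancer screening for
smokers and ex-smokers.

`lungcea` is for health-economic modellers who want a tested, configurable
implementation of a classic screening evaluation: a natural-history Markov
cohort model of lung cancer by histology (SCLC + four NSCLC types) and TNM
stage (IA–IV), annual LDCT screening scenarios with stage shift, discounted
cost/QALY accounting from the healthcare perspective, incremental
cost-effectiveness analysis with strict and extended dominance, and
probabilistic sensitivity analysis producing CEAC/CEAF curves.

## The model in brief

A closed cohort of 100,000 eligible smokers/ex-smokers (ten age groups of
10,000, entering at ages 50–95) is propagated in annual cycles to age 100.
Well persons develop preclinical cancer at an age-dependent onset rate and
present clinically at a late-heavy stage distribution; an active screening
programme detects prevalent preclinical cases each year with sensitivity
*s* at an early-heavy stage distribution instead (the stage shift).
Detected patients face stage-specific lung-cancer mortality, cure and
recurrence; everyone faces life-table other-cause mortality.

Costs (screening rounds, PET/biopsy confirmation, stage-specific
treatment, recurrence therapy, terminal palliative care) and utilities are
attached to the trace and discounted at 4%/1.5% per year.  For strategies
sorted by cost, sequential ICERs

&nbsp;&nbsp;&nbsp;&nbsp;ICER = ΔC / ΔE  (EUR per QALY gained)

are computed after removing strictly and extended-dominated strategies;
the survivors form the efficiency frontier.  The PSA perturbs every
probability/utility (beta) and cost (gamma) within ±10% ranges and reports,
per willingness-to-pay value λ, the probability that each strategy
maximizes the net monetary benefit NMB = λ·E − C (CEAC), and the frontier
of expected-NMB maximizers (CEAF).

Because the original registry/trial parameter values are not public, a
synthetic-data module generates complete, internally consistent parameter
sets with the right structure (documented in `docs/methods.md`); all
results below are for those synthetic study conditions.

## Worked example

```sh
lungcea generate --out fixture --seed 7
lungcea run --in fixture --out results
```

prints (EUR; totals per 100,000 persons):

```
    scenario note        cost       qalys   icer             status cost_vs_reference qalys_vs_reference    cer
no screening      269,009,583 1,008,327.3               on-frontier
       50-60    * 307,095,648 1,009,986.8        extended-dominated        38,086,065            1,659.5 22,950
       60-70      336,473,512 1,012,813.0 15,040        on-frontier        67,463,930            4,485.7 15,040
       50-70    * 374,635,169 1,014,332.0        extended-dominated       105,625,586            6,004.8 17,590
         70+    * 447,086,666 1,017,119.1        extended-dominated       178,077,083            8,791.8 20,255
         60+      514,756,304 1,021,354.1 20,874        on-frontier       245,746,721           13,026.8 18,865
         50+      552,917,960 1,022,873.1 25,123        on-frontier       283,908,378           14,545.8 19,518
* extended-dominated scenario; monetary amounts in EUR
```

Reading the table: each row is a screening window (start–stop age; `50+`
means lifelong from 50) sorted by total discounted cost.  Under this
synthetic parameter set, screening ages 60–70 buys QALYs at €15,040 each
versus no screening; widening the window adds QALYs at increasing
sequential ICERs (€20,874, then €25,123 per QALY), and three intermediate
windows are excluded by extended dominance (starred) because combinations
of their neighbours deliver QALYs more cheaply.  Vs-no-screening CERs sit
in the €15,000–23,000/QALY band.  The same analysis is available in
Python:

```python
from lungcea import (GeneratorConfig, generate_parameter_set,
                     generate_population, scenario_grid, evaluate_scenarios,
                     efficiency_frontier)

params, _ = generate_parameter_set(GeneratorConfig(seed=7))
ev = evaluate_scenarios(params, scenario_grid(), generate_population())
for entry in efficiency_frontier(ev.results):
    print(entry.label, entry.status, entry.icer)
```

`lungcea psa --in fixture --out psa --n-draws 5000 --seed 7` writes the
per-draw CE plane (`draws.csv`), the acceptability curves (`ceac.csv`) and
the frontier with its WTP switch-points (`ceaf.csv`,
`ceaf_switch_points.csv`).

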