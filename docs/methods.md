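# Methods

## Model overview

`lungcea` implements a decision-analytic Markov cohort model of low-dose CT
(LDCT) screening for lung cancer in heavy smokers and ex-smokers, evaluated
from the healthcare perspective over a lifetime horizon with annual cycles.

The health-state space distinguishes five histological types — SCLC plus
the four NSCLC types (adenocarcinoma, squamous-cell, large-cell, other
NSCLC) — and the seven TNM stage groups IA, IB, IIA, IIB, IIIA, IIIB, IV.
Besides five non-cancer states (well, post-treatment, recurrence, death
from lung cancer, death from other causes) there is one cancer state per
(histology, stage) pair, split into screen-detected and clinically-detected
variants: `5 + 2·5·7 = 75` public states.

Internally the engine additionally splits "well" into a healthy compartment
and one *preclinical* compartment per histology (undiagnosed prevalent
cancer, the mass a screening round can detect).  Both are undiagnosed, so
the public trace reports their sum as "well" and keeps the 75-state count.
The extended 80-state chain is a genuine linear time-varying Markov chain:
each cycle factors into three row-stochastic matrices (screening round,
onset/presentation, disease outcomes), and the fast vectorized engine is
cross-checked against propagation through the composed matrices to 1e-9
relative.

### Event order within a cycle

Fixed and documented: (1) screening round at cycle start, applied to the
preclinical mass carried over from earlier cycles; (2) onset (well →
preclinical) and clinical presentation (preclinical → clinically-detected
cancer, at the clinical stage distribution); (3) disease outcomes
(lung-cancer death, other-cause death, cure, within-stage progression) and
the post-treatment/recurrence transitions.  A consequence worth noting:
cases that onset in a given year cannot be screen-detected that same year
(interval cancers) and surface no earlier than the following cycle.

### Stage shift

Screen-detected cases receive the screen stage distribution (early-heavy,
emulating a trial second-round screen distribution); clinically presenting
cases receive the clinical distribution (late-heavy, emulating registry
stage at diagnosis).  Because the screened distribution is a convex mix of
the clinical distribution and an early-stage template, its cumulative mass
through every early stage dominates the clinical one by construction.
`apply_stage_shift` expresses the counterfactual reading of the same
assumption — each screen-detected early-stage case would otherwise have
presented at one of the last stages (default rule: stage IV with weight 1,
a IIIB/IV split is configurable).

### Detection cascade

LDCT positives are confirmed by PET and biopsy; the combined cascade is
assumed to produce no false positives.  False negatives (per-round
sensitivity below 1) remain in the preclinical compartment and are
screened again at the next annual round, giving the geometric carryover
`s, s(1-s), s(1-s)^2, ...` unless they present clinically in between.
Attendance is complete (no loss to follow-up); the per-round cost is
charged to every alive undiagnosed participant in the window.

### Cure and recurrence

Cure probability depends on histology and stage and moves patients to a
pooled post-treatment state.  From there an annual recurrence probability
moves them to the recurrence state.  Because the pooled post-treatment
state cannot carry histology, recurrence is modelled as its own
late-stage-equivalent state: stage-IV-like annual lung-cancer mortality
and a systemic-therapy treatment cost charged on entry.  This is the one
place the implementation deviates from re-entering an explicit
(histology, IV) cancer state; with a single pooled cured state the two
formulations differ only in bookkeeping granularity.

### Population and horizon

A closed multi-age cohort: ten age groups of 10,000 persons entering at
start ages 50, 55, …, 95 (100,000 in total), each simulated separately
under a common calendar clock and pooled, so totals are per 100,000.
Every cohort member satisfies the programme inclusion criteria (more than
30 smoking-years, at least 15 cigarettes/day, at most 10 years since
cessation).  Each group runs to age 100; by then, under the default
life-table (Gompertz hazard reaching ~0.5/year at 100), the surviving
fraction is negligible, so no separate early-stop rule is applied and all
traces stay rectangular (which keeps the matrix-product oracle and
budget-impact streams well-defined).

## Economics

* **Discounting** — 4%/year for costs, 1.5%/year for effects.
  End-of-cycle timing: cycle 0 undiscounted, cycle *t* divided by
  `(1+r)^t`; a begin-of-cycle switch exists in `DiscountSpec`.  Screening
  rounds happen at cycle start (exponent *t*); detections, recurrences and
  deaths resolve by cycle end (exponent *t+1*).  No half-cycle correction.
* **Costs** (single currency-year, EUR) — per-round screening cost for
  every attendee; PET+biopsy confirmation per screen positive; a lump-sum
  treatment cost at detection by histology and stage (surgery for
  resectable early stages, chemoradiation for stage III, systemic/
  immunotherapy for stage IV — one surgery price for all surgical
  interventions); a systemic-therapy cost per recurrence; palliative care
  for the terminal six months charged at each lung-cancer death and
  discounted at the death's cycle (annual cycles cannot resolve half
  years); an optional per-cycle chronic cost, zero by default.  A missing
  treatment entry for an occupied state raises an explicit error rather
  than pricing it at zero.
* **Utilities** — age-invariant state weights (survey-derived style):
  well 0.92, cancer by stage 0.80 → 0.55, post-treatment 0.85,
  recurrence 0.50, death 0.  QALYs value state membership at cycle end.

## Cost-effectiveness analysis

Strategies are sorted by increasing total discounted cost.  Strict
dominance removes strategies that cost at least as much as an alternative
without yielding more QALYs (equal cost keeps the higher-QALY strategy;
full ties keep the first by label order and warn).  Extended dominance
then iteratively removes any strategy whose sequential ICER is not below
the next one along, until the sequential ICERs strictly increase.  The
algorithm is verified against a brute-force upper-convex-hull oracle on
randomized instances, and against the published dominance pattern of the
embedded per-100,000 reference pairs (the three middle windows excluded by
extended dominance; frontier ICERs below the €20,000/QALY threshold).
CERs compare each strategy to no screening.  Budget impact is reported as
the undiscounted per-cycle incremental cost stream (standard
budget-impact convention; it sums to the undiscounted incremental total).

## Probabilistic sensitivity analysis

Each varied parameter carries a base value and a (lo, hi) range read as a
central 95% interval (the generator emits ±10% of base, clipped to the
support).  Probabilities and utilities draw from moment-matched beta
distributions, costs from gamma distributions; the mean always equals the
base value, and zero-width ranges degenerate to point masses so a
degenerate PSA reproduces the deterministic analysis bit for bit.  After
perturbation the stage-distribution rows are renormalized proportionally
(this preserves relative risks but introduces an O(variance) mean shift in
those cells — which is why the sampling-consistency checks are asserted on
scalar parameters).  Whole draws failing validation are redrawn with a
logged count.  All scenarios are evaluated under common random draws; draw
*d* always uses `SeedSequence(seed, spawn_key=(d,))`, so results are
order-independent and resumable by draw index.  CEAC probabilities split
exact ties equally and sum to 1 at every WTP; the CEAF selects the
expected-NMB maximizer (ties toward the cheaper strategy) and reports its
CEAC value; switch-points converge to the deterministic frontier ICERs as
the parameter variance vanishes.  The default WTP grid is €0–50,000 in
€100 steps.

## Synthetic study conditions

No registry (clinical stage/survival), trial (screen stage distribution)
or national cost data are distributed; the generator creates internally
consistent stand-ins with the right structure:

| parameter | default | rationale |
| --- | --- | --- |
| onset probability | logistic in age, ceiling 0.012, midpoint 60, slope 12 | ≈0.4%/yr at 50 rising to ≈1%/yr at 75+, the detection-rate range reported for heavy-smoking screening populations |
| presentation rate | 0.6/yr | mean preclinical sojourn under two years |
| lung-cancer mortality | 0.03/yr at IA × 1.55 per stage (SCLC ×1.7) | strictly increasing in stage, ≈0.45/yr at IV |
| cure probability | 0.30/yr at IA × 0.60 per stage (SCLC ×0.5) | early-stage disease is frequently curable, stage IV rarely |
| stage distributions | clinical ≈50% stage IV; screened = 0.2·clinical + 0.8·early template | late-heavy registry-like vs early-heavy screen-like |
| LDCT sensitivity | 0.90 | per-round, varied in the PSA |
| costs | LDCT round €300; confirmation €2,500; surgery €20k; chemoradiation €35k; systemic €45k; palliative €10k | surgery < chemoradiation < systemic ordering enforced |
| uncertainty width | ±10% | PSA ranges |

Magnitudes are jittered ±5% from seed to seed so property sweeps cover a
neighbourhood of the defaults, and every generated value is recorded in a
`SyntheticTruth` for test bookkeeping.  Under these conditions every
screening window gains QALYs at extra cost, wider windows weakly increase
both, and vs-no-screening CERs land in the €14,000–23,000/QALY range —
the right order of magnitude for published European LDCT evaluations.

What the generator does **not** emulate: calibration to any real registry
or trial, age-dependent stage-specific survival, smoking-cessation
dynamics, screening adherence below 100%, radiation harm, overdiagnosis
and lead-time correction (the latter four are deliberate model exclusions,
not generator shortcuts).  Passing tests therefore demonstrate the
*mechanics* — conservation, oracle equivalence, dominance arithmetic,
discounting, PSA consistency and the directional economics of stage shift
— not the reproduction of any published absolute total, sequential ICER
point value or CEAF switch-point, which depend on non-public parameter
values.

## Numerical choices

* Row-stochasticity is exact by construction (diagonals are remainders);
  validation tolerance 1e-9.
* Cohort conservation is checked to 1e-6 of cohort size; in practice the
  engine conserves to ~1e-12.
* Problem sizes: the default analysis is 7 strategies × 10 age groups ×
  ≤50 cycles (milliseconds per strategy); the test-suite PSA checks use
  10–60 draws and the acceptance summary uses 200 draws, sizes at which
  the Monte Carlo summaries reported are stable to well under the ±10%
  parameter uncertainty they propagate.  The CLI default of 5,000 draws
  matches common practice for production runs.
* Degenerate inputs: empty screening windows reproduce the no-screening
  trace bit for bit; zero sensitivity changes costs by exactly the
  accumulated programme spending and QALYs not at all; zero-width
  uncertainty reproduces the deterministic analysis exactly.

## Known limitations

* Progression after detection keeps the detection-variant label and does
  not re-charge treatment; chronic per-cycle costs default to zero.
* The recurrence state approximates a same-histology stage-IV relapse
  (see above).
* Other-cause mortality is shared by all cohort members (no
  smoker/ex-smoker split) and is not varied in the PSA.
* The screened and clinical stage distributions are independent inputs;
  the model does not derive one from the other via a tumour-growth model.
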