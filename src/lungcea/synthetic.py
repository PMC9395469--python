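"""Synthetic, internally consistent parameter sets and populations.

No registry or trial inputs are distributed with the package; this module
generates complete parameter sets with the right *structure* so that every
pipeline stage is exercisable end to end:

* annual lung-cancer mortality rising geometrically with stage (SCLC worst);
* cure probability falling with stage;
* a clinically-detected stage distribution concentrated in late stages
  (registry-like) and a screen-detected distribution shifted toward early
  stages (trial-round-2-like) by a configurable strength;
* treatment costs with early-stage surgery cheaper than late-stage
  systemic/immunotherapy, plus palliative costs for the terminal half-year;
* utilities decreasing with stage;
* beta/gamma uncertainty ranges of a configurable width.

All magnitudes are synthetic defaults chosen to be epidemiologically
plausible for a heavy-smoking cohort; they are jittered a few percent from
seed to seed so property tests sweep a neighbourhood of the defaults, and
every generated value is recorded in a :class:`SyntheticTruth` for test
bookkeeping.  Generation is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import MAX_AGE, ParameterSet, gompertz_mortality
from .psa import UncertaintyEntry, UncertaintySpec
from .screening import EligibilityProfile
from .states import ConfigurationError, StateSpace, build_state_space

#: Registry-like histology proportions (SCLC, adeno, squamous, large, other).
HISTOLOGY_MIX = np.array([0.15, 0.40, 0.25, 0.10, 0.10])
#: Multipliers on stage-IA lung-cancer mortality by histology.
HISTOLOGY_MORTALITY_MULT = np.array([1.7, 0.95, 1.0, 1.15, 1.05])
#: Multipliers on the cure probability by histology (SCLC rarely curable).
HISTOLOGY_CURE_MULT = np.array([0.5, 1.05, 1.0, 0.9, 0.95])

#: Late-heavy clinical stage-at-diagnosis template (IA..IV).
CLINICAL_STAGE_TEMPLATE = np.array([0.055, 0.045, 0.04, 0.05, 0.11, 0.20, 0.50])
#: Early-heavy screen-detected template.
SCREEN_STAGE_TEMPLATE = np.array([0.42, 0.20, 0.10, 0.09, 0.09, 0.06, 0.04])


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_age_groups: int = 10
    group_size: int = 10_000
    youngest_start_age: int = 50
    age_band_width: int = 5
    onset_scale: float = 0.012            # annual onset probability ceiling
    onset_midpoint: float = 60.0
    onset_slope: float = 12.0
    presentation_rate: float = 0.6        # preclinical -> clinical per year
    base_lc_mortality: float = 0.03       # stage-IA annual lung-cancer mortality
    stage_severity_ratio: float = 1.55    # geometric ladder across stages
    cure_base: float = 0.30               # stage-IA annual cure probability
    cure_decay: float = 0.60
    progression_rate: float = 0.15
    recurrence_rate: float = 0.05
    sensitivity: float = 0.90             # LDCT per-round sensitivity
    stage_shift_strength: float = 0.8     # 0 = no shift, 1 = full early template
    cost_screening_round: float = 300.0
    cost_confirmation: float = 2500.0
    cost_surgery: float = 20_000.0
    cost_chemoradiation: float = 35_000.0
    cost_systemic: float = 45_000.0       # immunotherapy-based, stage IV
    cost_palliative: float = 10_000.0
    utility_well: float = 0.92
    utility_stage_early: float = 0.80
    utility_stage_late: float = 0.55
    utility_post_treatment: float = 0.85
    utility_recurrence: float = 0.50
    uncertainty_width: float = 0.10       # half-width of PSA ranges, relative
    jitter: float = 0.05                  # seed-to-seed relative variation
    discount_cost: float = 0.04
    discount_qaly: float = 0.015

    def __post_init__(self):
        if not 0.0 <= self.stage_shift_strength <= 1.0:
            raise ConfigurationError("stage_shift_strength must be in [0, 1]")
        for name in ("onset_scale", "group_size", "n_age_groups", "cost_surgery",
                     "cost_chemoradiation", "cost_systemic", "cost_screening_round",
                     "base_lc_mortality", "cure_base", "sensitivity"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.jitter < 0 or self.jitter >= 0.5:
            raise ConfigurationError("jitter must be in [0, 0.5)")


@dataclass
class SyntheticTruth:
    """Record of every generated parameter, for test assertions."""

    parameters: dict[str, float]
    histology_mix: np.ndarray
    mortality: np.ndarray
    config: GeneratorConfig


def generate_parameter_set(config: GeneratorConfig | None = None,
                           seed: int | None = None
                           ) -> tuple[ParameterSet, SyntheticTruth]:
    """Generate a complete, valid ParameterSet (and its truth record)."""
    if config is None:
        config = GeneratorConfig(seed=0 if seed is None else seed)
    rng = np.random.default_rng(config.seed)
    j = config.jitter

    def u(size=None):
        return rng.uniform(1.0 - j, 1.0 + j, size=size)

    space = build_state_space()
    H, S = space.n_histologies, space.n_stages
    stage_idx = np.arange(S)

    p_lc = (config.base_lc_mortality * u()
            * HISTOLOGY_MORTALITY_MULT[:, None]
            * config.stage_severity_ratio ** stage_idx[None, :])
    p_lc = np.minimum(p_lc, 0.95)
    if np.any(np.diff(p_lc, axis=1) <= 0):
        raise ConfigurationError("stage-severity gradient does not increase mortality")

    p_cure = (config.cure_base * u()
              * HISTOLOGY_CURE_MULT[:, None]
              * config.cure_decay ** stage_idx[None, :])
    p_cure = np.clip(p_cure, 0.0, 1.0)

    clin = CLINICAL_STAGE_TEMPLATE[None, :] * u((H, S))
    clin /= clin.sum(axis=1, keepdims=True)
    sigma = config.stage_shift_strength
    if sigma == 0.0:
        scr = clin.copy()
    else:
        # convex mix with the early-heavy template: the screened cumulative
        # distribution dominates the clinical one toward early stages
        scr = (1.0 - sigma) * clin + sigma * SCREEN_STAGE_TEMPLATE[None, :]

    cost_treat = np.empty((H, S))
    surgery = config.cost_surgery * u()
    chemo = config.cost_chemoradiation * u()
    systemic = config.cost_systemic * u()
    early = stage_idx <= 3          # IA..IIB resectable
    mid = (stage_idx > 3) & (stage_idx < S - 1)
    for h in range(H):
        if space.histologies[h] == "SCLC":      # rarely resectable
            cost_treat[h, :] = np.where(stage_idx < S - 1, chemo * 0.9, systemic * 0.95)
        else:
            cost_treat[h, early] = surgery * (1.0 + 0.03 * stage_idx[early])
            cost_treat[h, mid] = chemo
            cost_treat[h, ~early & ~mid] = systemic
    if cost_treat[:, early].max() >= cost_treat[:, -1].min():
        raise ConfigurationError("early-stage treatment cost must stay below late-stage")

    utility_stage = np.linspace(config.utility_stage_early, config.utility_stage_late, S)

    params = ParameterSet(
        space=space,
        histology_mix=HISTOLOGY_MIX.copy(),
        onset_scale=min(config.onset_scale * u(), 1.0),
        onset_midpoint=config.onset_midpoint,
        onset_slope=config.onset_slope,
        presentation_rate=min(config.presentation_rate * u(), 1.0),
        p_lc_death=p_lc,
        p_cure=p_cure,
        progression_rate=min(config.progression_rate * u(), 1.0),
        recurrence_rate=min(config.recurrence_rate * u(), 1.0),
        recurrence_lc_mortality=float(np.mean(p_lc[:, -1])),
        other_cause_mortality=gompertz_mortality(),
        stage_dist_clinical=clin,
        stage_dist_screened=scr,
        sensitivity=min(config.sensitivity * u(), 1.0),
        cost_screening_round=config.cost_screening_round * u(),
        cost_confirmation=config.cost_confirmation * u(),
        cost_palliative=config.cost_palliative * u(),
        cost_recurrence=systemic,
        cost_treatment=cost_treat,
        utility_well=config.utility_well,
        utility_post_treatment=config.utility_post_treatment,
        utility_recurrence=config.utility_recurrence,
        utility_stage=utility_stage,
        discount_cost=config.discount_cost,
        discount_qaly=config.discount_qaly,
    )
    params.require_valid()
    truth = SyntheticTruth(
        parameters={pid: params.get_param(pid) for pid in params.psa_parameter_ids()},
        histology_mix=params.histology_mix.copy(),
        mortality=params.other_cause_mortality.copy(),
        config=config,
    )
    return params, truth


def generate_population(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Per-age-group counts of eligible smokers/ex-smokers.

    Ten groups of 10,000 by default (100,000 in total), entering at start
    ages 50, 55, ..., 95; the smoking-prevalence column is contextual
    (declining with age) and does not scale the counts, which are fixed by
    design.
    """
    config = config or GeneratorConfig()
    start_ages = config.youngest_start_age + config.age_band_width * np.arange(config.n_age_groups)
    if start_ages.max() >= MAX_AGE:
        raise ConfigurationError("age groups extend beyond the model's maximum age")
    prevalence = np.clip(0.25 - 0.0035 * (start_ages - 50), 0.05, None)
    return pd.DataFrame({
        "group": [f"{a}-{a + config.age_band_width - 1}" for a in start_ages],
        "start_age": start_ages,
        "count": config.group_size,
        "smoking_prevalence": prevalence,
    })


def generate_profiles(config: GeneratorConfig | None = None,
                      n_per_group: int = 100) -> pd.DataFrame:
    """Individual eligibility profiles, all satisfying the inclusion criteria
    (> 30 smoking-years, >= 15 cigarettes/day, quit <= 10 years ago)."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed + 1)
    pop = generate_population(config)
    rows = []
    for row in pop.itertuples(index=False):
        age = row.start_age + rng.uniform(0, config.age_band_width, n_per_group)
        years_smoked = rng.uniform(31, np.maximum(age - 15, 32))
        cigs = rng.uniform(15, 40, n_per_group)
        current = rng.random(n_per_group) < 0.6
        quit_years = np.where(current, 0.0, rng.uniform(0, 10, n_per_group))
        for k in range(n_per_group):
            rows.append((row.group, age[k], years_smoked[k], cigs[k], quit_years[k]))
    frame = pd.DataFrame(rows, columns=["group", "age", "years_smoked",
                                        "cigarettes_per_day", "years_since_cessation"])
    return frame


def profiles_to_objects(frame: pd.DataFrame) -> list[EligibilityProfile]:
    return [EligibilityProfile(r.age, r.years_smoked, r.cigarettes_per_day,
                               r.years_since_cessation)
            for r in frame.itertuples(index=False)]


def generate_uncertainty_spec(params: ParameterSet,
                              width: float = 0.10) -> UncertaintySpec:
    """Uncertainty ranges of +/- ``width`` times base (clipped to support)
    for every PSA parameter: beta for probabilities/utilities, gamma for
    costs.  ``width=0`` yields a degenerate spec reproducing the
    deterministic analysis."""
    if width < 0:
        raise ValueError("width must be >= 0")
    spec = UncertaintySpec()
    for pid in params.psa_parameter_ids():
        base = params.get_param(pid)
        family = params.param_family(pid)
        lo = base * (1.0 - width)
        hi = base * (1.0 + width)
        if family == "beta":
            lo, hi = max(lo, 0.0), min(hi, 1.0)
        spec.add(UncertaintyEntry(pid, base, family, lo, hi))
    return spec
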