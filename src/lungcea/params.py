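"""Complete model input: natural history, screening, costs, utilities.

A :class:`ParameterSet` is the single object the cohort engine, the
economics layer and the probabilistic sensitivity analysis consume.  Every
scalar or cell that the PSA may vary is addressable through a flat dotted
identifier such as ``"cure.adenocarcinoma.IA"`` or
``"cost.treatment.SCLC.IV"`` (see :meth:`ParameterSet.psa_parameter_ids`).

Disease dynamics
----------------
* onset: annual probability that a well person develops lung cancer,
  logistic in age (``scale / (1 + exp(-(age - midpoint)/slope))``);
* presentation: annual probability that an undiagnosed (preclinical) case
  surfaces clinically, at the clinical (registry-like) stage distribution;
* screen detection replaces clinical presentation for the fraction caught
  by LDCT, at the screen (trial-round-2-like) stage distribution;
* detected cases face stage-specific annual lung-cancer mortality
  (non-decreasing in stage), an annual cure probability (to the
  post-treatment state), and within-stage progression;
* cured patients may recur; the recurrence state carries stage-IV-like
  lung-cancer mortality;
* everyone faces age-indexed other-cause mortality (life-table style).
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np

from .states import ConfigurationError, StateSpace, build_state_space

MAX_AGE = 120


class ParameterError(ValueError):
    """Raised when a ParameterSet fails validation."""

    def __init__(self, issues):
        self.issues = list(issues)
        super().__init__("invalid ParameterSet:\n" + "\n".join(self.issues))


_SCALAR_ATTRS = {
    "onset.scale": "onset_scale",
    "onset.midpoint": "onset_midpoint",
    "onset.slope": "onset_slope",
    "onset.presentation": "presentation_rate",
    "progression.rate": "progression_rate",
    "recurrence.rate": "recurrence_rate",
    "recurrence.lc_mortality": "recurrence_lc_mortality",
    "screening.sensitivity": "sensitivity",
    "cost.screening_round": "cost_screening_round",
    "cost.confirmation": "cost_confirmation",
    "cost.palliative": "cost_palliative",
    "cost.recurrence": "cost_recurrence",
    "utility.well": "utility_well",
    "utility.post_treatment": "utility_post_treatment",
    "utility.recurrence": "utility_recurrence",
    "discount.cost": "discount_cost",
    "discount.effect": "discount_qaly",
}

_GRID_ATTRS = {
    "lc_mortality": "p_lc_death",
    "cure": "p_cure",
    "stage_dist.clinical": "stage_dist_clinical",
    "stage_dist.screened": "stage_dist_screened",
    "cost.treatment": "cost_treatment",
    "cost.chronic": "cost_chronic",
}


@dataclass
class ParameterSet:
    space: StateSpace
    histology_mix: np.ndarray                 # (H,) sums to 1
    onset_scale: float
    onset_midpoint: float
    onset_slope: float
    presentation_rate: float                  # preclinical -> clinical per year
    p_lc_death: np.ndarray                    # (H, S) annual lung-cancer mortality
    p_cure: np.ndarray                        # (H, S) annual cure probability
    progression_rate: float                   # within-patient stage progression per year
    recurrence_rate: float                    # post-treatment -> recurrence per year
    recurrence_lc_mortality: float            # recurrence-state lung-cancer mortality
    other_cause_mortality: np.ndarray         # indexed by age 0..MAX_AGE
    stage_dist_clinical: np.ndarray           # (H, S) rows sum to 1
    stage_dist_screened: np.ndarray           # (H, S) rows sum to 1
    sensitivity: float                        # LDCT per-round sensitivity
    cost_screening_round: float               # EUR per attended round
    cost_confirmation: float                  # EUR per screen-positive (PET + biopsy)
    cost_palliative: float                    # EUR, terminal six months
    cost_recurrence: float                    # EUR per recurrence (systemic therapy)
    cost_treatment: np.ndarray                # (H, S) EUR, lump sum at detection
    cost_chronic: np.ndarray = None           # (H, S) EUR per cycle in state (default 0)
    utility_well: float = 0.92
    utility_post_treatment: float = 0.85
    utility_recurrence: float = 0.50
    utility_stage: np.ndarray = None          # (S,) cancer-state utility by stage
    discount_cost: float = 0.04
    discount_qaly: float = 0.015
    currency: str = "EUR"

    def __post_init__(self):
        H, S = self.space.n_histologies, self.space.n_stages
        if self.cost_chronic is None:
            self.cost_chronic = np.zeros((H, S))
        if self.utility_stage is None:
            self.utility_stage = np.linspace(0.80, 0.55, S)
        for name in ("histology_mix", "p_lc_death", "p_cure", "stage_dist_clinical",
                     "stage_dist_screened", "cost_treatment", "cost_chronic",
                     "utility_stage", "other_cause_mortality"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    # ------------------------------------------------------------------ age
    def onset_probability(self, age: float) -> float:
        return self.onset_scale / (1.0 + np.exp(-(age - self.onset_midpoint) / self.onset_slope))

    def mortality(self, age: int) -> float:
        idx = min(max(int(age), 0), len(self.other_cause_mortality) - 1)
        return float(self.other_cause_mortality[idx])

    # ----------------------------------------------------------- validation
    def validate(self) -> list[str]:
        """Return a list of human-readable invariant violations (empty iff valid)."""
        issues: list[str] = []
        H, S = self.space.n_histologies, self.space.n_stages

        def shape(name, arr, expect):
            if arr.shape != expect:
                issues.append(f"{name} has shape {arr.shape}, expected {expect}")
                return False
            return True

        shape("histology_mix", self.histology_mix, (H,))
        for name in ("p_lc_death", "p_cure", "stage_dist_clinical",
                     "stage_dist_screened", "cost_treatment", "cost_chronic"):
            shape(name, getattr(self, name), (H, S))
        if abs(self.histology_mix.sum() - 1.0) > 1e-9:
            issues.append(f"histology_mix sums to {self.histology_mix.sum():.12f}, expected 1")
        for name in ("onset_scale", "presentation_rate", "progression_rate",
                     "recurrence_rate", "recurrence_lc_mortality", "sensitivity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                issues.append(f"{name} = {v} outside [0, 1]")
        for name in ("p_lc_death", "p_cure", "stage_dist_clinical", "stage_dist_screened"):
            arr = getattr(self, name)
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                issues.append(f"{name} has entries outside [0, 1]")
        for name in ("stage_dist_clinical", "stage_dist_screened"):
            arr = getattr(self, name)
            if arr.shape == (H, S):
                bad = np.abs(arr.sum(axis=1) - 1.0) > 1e-9
                for i in np.flatnonzero(bad):
                    issues.append(
                        f"{name} row for {self.space.histologies[i]} sums to "
                        f"{arr[i].sum():.12f}, expected 1"
                    )
        if self.p_lc_death.shape == (H, S):
            if np.any(np.diff(self.p_lc_death, axis=1) < 0):
                issues.append("p_lc_death must be non-decreasing in stage for each histology")
        if self.other_cause_mortality.min() < 0 or self.other_cause_mortality.max() > 1:
            issues.append("other_cause_mortality outside [0, 1]")
        for name in ("cost_screening_round", "cost_confirmation", "cost_palliative",
                     "cost_recurrence"):
            if getattr(self, name) < 0:
                issues.append(f"{name} is negative")
        if self.cost_treatment.min() < 0 or self.cost_chronic.min() < 0:
            issues.append("treatment/chronic costs must be non-negative")
        for name in ("utility_well", "utility_post_treatment", "utility_recurrence"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                issues.append(f"{name} = {v} outside [-1, 1]")
        if self.utility_stage.min() < -1 or self.utility_stage.max() > 1:
            issues.append("utility_stage outside [-1, 1]")
        if self.utility_stage.size and self.utility_well < self.utility_stage.max() - 1e-12:
            issues.append("well-state utility must be >= every cancer-state utility")
        if self.discount_cost < 0 or self.discount_qaly < 0:
            issues.append("discount rates must be >= 0")
        return issues

    def require_valid(self) -> None:
        issues = self.validate()
        if issues:
            raise ParameterError(issues)

    def copy(self) -> "ParameterSet":
        return _copy.deepcopy(self)

    # -------------------------------------------------- flat parameter ids
    def _grid_loc(self, pid: str):
        for prefix, attr in _GRID_ATTRS.items():
            if pid.startswith(prefix + "."):
                rest = pid[len(prefix) + 1:]
                h, _, s = rest.rpartition(".")
                try:
                    return attr, self.space.histologies.index(h), self.space.stages.index(s)
                except ValueError:
                    raise KeyError(f"unknown parameter id: {pid}") from None
        return None

    def get_param(self, pid: str) -> float:
        if pid in _SCALAR_ATTRS:
            return float(getattr(self, _SCALAR_ATTRS[pid]))
        if pid.startswith("utility.stage."):
            return float(self.utility_stage[self.space.stages.index(pid.rsplit(".", 1)[1])])
        loc = self._grid_loc(pid)
        if loc is not None:
            attr, i, j = loc
            return float(getattr(self, attr)[i, j])
        raise KeyError(f"unknown parameter id: {pid}")

    def set_param(self, pid: str, value: float) -> None:
        if pid in _SCALAR_ATTRS:
            setattr(self, _SCALAR_ATTRS[pid], float(value))
            return
        if pid.startswith("utility.stage."):
            self.utility_stage[self.space.stages.index(pid.rsplit(".", 1)[1])] = float(value)
            return
        loc = self._grid_loc(pid)
        if loc is not None:
            attr, i, j = loc
            getattr(self, attr)[i, j] = float(value)
            return
        raise KeyError(f"unknown parameter id: {pid}")

    def psa_parameter_ids(self) -> list[str]:
        """Ordered ids of the parameters varied in probabilistic sensitivity analysis.

        Probabilities and utilities draw from beta distributions, costs from
        gamma distributions; background (other-cause) mortality and the onset
        age-curve shape are held fixed.
        """
        ids = [
            "screening.sensitivity",
            "onset.scale",
            "onset.presentation",
            "progression.rate",
            "recurrence.rate",
            "recurrence.lc_mortality",
        ]
        hs = [(h, s) for h in self.space.histologies for s in self.space.stages]
        ids += [f"lc_mortality.{h}.{s}" for h, s in hs]
        ids += [f"cure.{h}.{s}" for h, s in hs]
        ids += [f"stage_dist.clinical.{h}.{s}" for h, s in hs]
        ids += [f"stage_dist.screened.{h}.{s}" for h, s in hs]
        ids += ["utility.well", "utility.post_treatment", "utility.recurrence"]
        ids += [f"utility.stage.{s}" for s in self.space.stages]
        ids += ["cost.screening_round", "cost.confirmation", "cost.palliative",
                "cost.recurrence"]
        ids += [f"cost.treatment.{h}.{s}" for h, s in hs]
        return ids

    @staticmethod
    def param_family(pid: str) -> str:
        """Distribution family for PSA: gamma for costs, beta otherwise."""
        return "gamma" if pid.startswith("cost.") else "beta"

    # ------------------------------------------------------------- adapters
    def cost_table(self):
        from .economics import CostTable
        return CostTable(
            space=self.space,
            screening_round=self.cost_screening_round,
            confirmation=self.cost_confirmation,
            palliative=self.cost_palliative,
            recurrence=self.cost_recurrence,
            treatment=self.cost_treatment.copy(),
            chronic=self.cost_chronic.copy(),
            currency=self.currency,
        )

    def utility_table(self):
        from .economics import UtilityTable
        return UtilityTable(
            space=self.space,
            well=self.utility_well,
            post_treatment=self.utility_post_treatment,
            recurrence=self.utility_recurrence,
            stage=self.utility_stage.copy(),
        )

    def discount_spec(self):
        from .economics import DiscountSpec
        return DiscountSpec(cost_rate=self.discount_cost, effect_rate=self.discount_qaly)


def gompertz_mortality(a0: float = 0.004, b: float = 0.09, pivot_age: int = 50,
                       floor: float = 0.0015, cap: float = 0.98) -> np.ndarray:
    """Life-table-style annual all-cause mortality, ages 0..MAX_AGE.

    Gompertz above ``pivot_age``, a small flat hazard below; capped so the
    array stays a probability.  Emulates a WHO life table for a smoking
    population without reproducing any published table.
    """
    ages = np.arange(MAX_AGE + 1)
    q = np.where(ages < pivot_age, floor, a0 * np.exp(b * (ages - pivot_age)))
    return np.minimum(np.maximum(q, floor), cap)


def disease_free_parameters(space: StateSpace | None = None,
                            mortality: np.ndarray | None = None) -> ParameterSet:
    """A valid ParameterSet with zero cancer onset (life-table collapse)."""
    space = space or build_state_space()
    H, S = space.n_histologies, space.n_stages
    return ParameterSet(
        space=space,
        histology_mix=np.full(H, 1.0 / H),
        onset_scale=0.0, onset_midpoint=70.0, onset_slope=8.0,
        presentation_rate=0.6,
        p_lc_death=np.tile(np.linspace(0.05, 0.4, S), (H, 1)),
        p_cure=np.tile(np.linspace(0.3, 0.02, S), (H, 1)),
        progression_rate=0.15, recurrence_rate=0.05, recurrence_lc_mortality=0.4,
        other_cause_mortality=mortality if mortality is not None else gompertz_mortality(),
        stage_dist_clinical=np.full((H, S), 1.0 / S),
        stage_dist_screened=np.full((H, S), 1.0 / S),
        sensitivity=0.9,
        cost_screening_round=250.0, cost_confirmation=2500.0,
        cost_palliative=10_000.0, cost_recurrence=45_000.0,
        cost_treatment=np.tile(np.linspace(20_000.0, 45_000.0, S), (H, 1)),
    )
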