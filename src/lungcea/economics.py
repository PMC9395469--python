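"""Costs, utilities and discounted accumulation over a cohort trace.

Costs are taken from the healthcare perspective: a per-round screening
cost for every attendee, a confirmation (PET + biopsy) cost per screen
positive, a lump-sum treatment cost per detected case by histology and
stage, a systemic-therapy cost per recurrence, a palliative-care cost for
the terminal six months charged at each lung-cancer death, and an optional
per-cycle chronic cost (default zero).  QALYs weight each person-year by
an age-invariant state utility.  Costs and effects are discounted at
separate annual rates (defaults 4% and 1.5%); by the end-of-cycle timing
convention cycle 0 is undiscounted and cycle ``t`` is divided by
``(1 + r) ** t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import NON_CANCER_STATES, StateSpace

COST_CATEGORIES = ("screening", "confirmation", "treatment", "recurrence",
                   "palliative", "chronic")


class MissingCostError(KeyError):
    """A cost entry required by an occupied state/event is absent."""


@dataclass(frozen=True)
class DiscountSpec:
    """Differential annual discounting for costs and effects."""

    cost_rate: float = 0.04
    effect_rate: float = 0.015
    timing: str = "end"   # "end": cycle t / (1+r)^t; "begin": cycle t / (1+r)^(t-1)

    def __post_init__(self):
        if self.cost_rate < 0 or self.effect_rate < 0:
            raise ValueError("discount rates must be >= 0")
        if self.timing not in ("end", "begin"):
            raise ValueError("timing must be 'end' or 'begin'")


def discount_factor(rate: float, cycle_index, timing: str = "end"):
    """``1 / (1 + rate) ** t`` under the chosen timing convention."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    t = np.asarray(cycle_index, dtype=float)
    if np.any(t < 0):
        raise ValueError("cycle_index must be >= 0")
    if timing == "begin":
        t = np.maximum(t - 1.0, 0.0)
    return (1.0 + rate) ** -t


@dataclass
class CostTable:
    space: StateSpace
    screening_round: float
    confirmation: float
    palliative: float
    recurrence: float
    treatment: np.ndarray          # (H, S) EUR per detected case
    chronic: np.ndarray = None     # (H, S) EUR per person-cycle in state
    currency: str = "EUR"

    def __post_init__(self):
        if self.chronic is None:
            self.chronic = np.zeros_like(np.asarray(self.treatment, dtype=float))
        self.treatment = np.asarray(self.treatment, dtype=float)
        self.chronic = np.asarray(self.chronic, dtype=float)
        shape = (self.space.n_histologies, self.space.n_stages)
        if self.treatment.shape != shape:
            raise MissingCostError(f"treatment cost table has shape {self.treatment.shape},"
                                   f" expected {shape}")
        if np.isnan(self.treatment).any():
            h, s = np.argwhere(np.isnan(self.treatment))[0]
            raise MissingCostError(
                "missing treatment cost for "
                f"{self.space.histologies[h]}/{self.space.stages[s]}"
            )
        for name in ("screening_round", "confirmation", "palliative", "recurrence"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} cost is negative")
        if self.treatment.min() < 0 or self.chronic.min() < 0:
            raise ValueError("treatment/chronic costs must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        rows = [("screening_round", "", "", self.screening_round),
                ("confirmation", "", "", self.confirmation),
                ("palliative", "", "", self.palliative),
                ("recurrence", "", "", self.recurrence)]
        for i, h in enumerate(self.space.histologies):
            for j, s in enumerate(self.space.stages):
                rows.append(("treatment", h, s, self.treatment[i, j]))
                if self.chronic[i, j]:
                    rows.append(("chronic", h, s, self.chronic[i, j]))
        return pd.DataFrame(rows, columns=["category", "histology", "stage", "amount_eur"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, space: StateSpace,
                   currency: str = "EUR") -> "CostTable":
        frame = frame.fillna({"histology": "", "stage": ""})
        scalars = {}
        treatment = np.full((space.n_histologies, space.n_stages), np.nan)
        chronic = np.zeros_like(treatment)
        for row in frame.itertuples(index=False):
            if row.category in ("treatment", "chronic"):
                i = space.histologies.index(row.histology)
                j = space.stages.index(row.stage)
                (treatment if row.category == "treatment" else chronic)[i, j] = row.amount_eur
            else:
                scalars[row.category] = float(row.amount_eur)
        missing = {"screening_round", "confirmation", "palliative", "recurrence"} - set(scalars)
        if missing:
            raise MissingCostError(f"missing cost categories: {sorted(missing)}")
        return cls(space=space, treatment=treatment, chronic=chronic, currency=currency,
                   **{k: scalars[k] for k in
                      ("screening_round", "confirmation", "palliative", "recurrence")})


@dataclass
class UtilityTable:
    """Age-invariant utility weight per health state; death weighs zero."""

    space: StateSpace
    well: float
    post_treatment: float
    recurrence: float
    stage: np.ndarray              # (S,) cancer-state utility by stage

    def __post_init__(self):
        self.stage = np.asarray(self.stage, dtype=float)
        vals = np.concatenate([[self.well, self.post_treatment, self.recurrence], self.stage])
        if vals.min() < -1 or vals.max() > 1:
            raise ValueError("utilities must lie in [-1, 1]")
        if self.stage.size and self.well < self.stage.max() - 1e-12:
            raise ValueError("well-state utility must be >= every cancer-state utility")

    def state_vector(self) -> np.ndarray:
        """Utilities aligned with the public state ordering."""
        sp = self.space
        u = np.zeros(sp.n_states)
        u[sp.index("well")] = self.well
        u[sp.index("post_treatment")] = self.post_treatment
        u[sp.index("recurrence")] = self.recurrence
        for h in range(sp.n_histologies):
            for s in range(sp.n_stages):
                for v in range(2):
                    u[sp.cancer_index(h, s, v)] = self.stage[s]
        return u

    def to_frame(self) -> pd.DataFrame:
        rows = [("well", self.well), ("post_treatment", self.post_treatment),
                ("recurrence", self.recurrence),
                ("death_lung_cancer", 0.0), ("death_other", 0.0)]
        rows += [(f"stage|{s}", self.stage[j]) for j, s in enumerate(self.space.stages)]
        return pd.DataFrame(rows, columns=["state", "utility"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, space: StateSpace) -> "UtilityTable":
        vals = dict(zip(frame["state"], frame["utility"].astype(float)))
        stage = np.array([vals[f"stage|{s}"] for s in space.stages])
        return cls(space=space, well=vals["well"], post_treatment=vals["post_treatment"],
                   recurrence=vals["recurrence"], stage=stage)


# ----------------------------------------------------------- accumulation
def cost_streams(trace, events: dict, costs: CostTable) -> dict[str, np.ndarray]:
    """Undiscounted per-calendar-cycle cost streams by category.

    Streams have length ``horizon + 1``: screening-round spending lands at
    the round's cycle index ``t``; detection, recurrence and palliative
    spending resolve at ``t + 1``.
    """
    T = trace.horizon
    streams = {cat: np.zeros(T + 1) for cat in COST_CATEGORIES}
    if events is None:
        raise ValueError("cost accumulation requires the event streams of the fast engine")
    streams["screening"][:T] = events["attended"] * costs.screening_round
    streams["confirmation"][:T] = events["screen_detected"] * costs.confirmation
    treat = np.einsum("ths,hs->t", events["inflow_screen"], costs.treatment)
    treat_clin = np.einsum("ths,hs->t", events["inflow_clinical"], costs.treatment)
    # screen detections are confirmed and treated from the round onwards, but the
    # treatment episode runs through the year; both inflows are valued at cycle end
    streams["treatment"][1:] = treat + treat_clin
    streams["recurrence"][1:] = events["recurrence_entries"] * costs.recurrence
    streams["palliative"][1:] = events["lc_deaths"] * costs.palliative
    if costs.chronic.any():
        sp = trace.space
        occ = trace.data[:, len(NON_CANCER_STATES):]
        occ = occ.reshape(occ.shape[0], sp.n_histologies, sp.n_stages, 2).sum(axis=3)
        streams["chronic"][1:] = np.einsum("ths,hs->t", occ[1:], costs.chronic)
    return streams


def accumulate_costs(trace, events: dict, costs: CostTable,
                     spec: DiscountSpec | None = None) -> float:
    """Total discounted cost of a cohort run (additive over categories)."""
    spec = spec or DiscountSpec()
    streams = cost_streams(trace, events, costs)
    df = discount_factor(spec.cost_rate, np.arange(trace.horizon + 1), spec.timing)
    return float(sum((s * df).sum() for s in streams.values()))


def cost_breakdown(trace, events: dict, costs: CostTable,
                   spec: DiscountSpec | None = None) -> dict[str, float]:
    spec = spec or DiscountSpec()
    streams = cost_streams(trace, events, costs)
    df = discount_factor(spec.cost_rate, np.arange(trace.horizon + 1), spec.timing)
    return {cat: float((s * df).sum()) for cat, s in streams.items()}


def terminal_palliative_costs(events: dict, costs: CostTable,
                              spec: DiscountSpec | None = None) -> float:
    """Discounted palliative-care cost charged at each lung-cancer death."""
    spec = spec or DiscountSpec()
    deaths = events["lc_deaths"]
    df = discount_factor(spec.cost_rate, np.arange(1, deaths.size + 1), spec.timing)
    return float((deaths * costs.palliative * df).sum())


def accumulate_qalys(trace, utilities: UtilityTable,
                     spec: DiscountSpec | None = None) -> float:
    """Total discounted QALYs: occupancy x utility x effect discount factor.

    Person-year ``t`` is valued by state membership at cycle end (trace row
    ``t``, ``t >= 1``).
    """
    spec = spec or DiscountSpec()
    u = utilities.state_vector()
    df = discount_factor(spec.effect_rate, np.arange(1, trace.horizon + 1), spec.timing)
    return float((trace.data[1:] @ u * df).sum())


def accumulate_life_years(trace, spec: DiscountSpec | None = None) -> float:
    """Discounted life-years (utility 1 for every living state)."""
    sp = trace.space
    ones = UtilityTable(space=sp, well=1.0, post_treatment=1.0, recurrence=1.0,
                        stage=np.ones(sp.n_stages))
    return accumulate_qalys(trace, ones, spec)
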