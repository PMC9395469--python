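"""Screening scenarios, eligibility, detection rounds and stage shift.

A screening scenario is an annual LDCT programme between a start and a stop
age (or lifelong).  The diagnostic cascade is LDCT followed by PET and
biopsy for positives; the combined cascade is assumed to produce no false
positives, and false negatives remain undiagnosed and are eligible again at
the next round.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .states import ConfigurationError

LIFETIME = "lifetime"

#: Start/stop grid of the evaluated programme variants.
DEFAULT_START_AGES = (50, 60, 70)
DEFAULT_STOP_AGES = (60, 70, LIFETIME)

NO_SCREENING_LABEL = "no screening"


def _default_label(start_age, stop_age) -> str:
    return f"{start_age}+" if stop_age == LIFETIME else f"{start_age}-{stop_age}"


@dataclass(frozen=True)
class ScreeningScenario:
    """Annual screening window ``[start_age, stop_age)``; ``stop_age`` may be "lifetime"."""

    start_age: int
    stop_age: int | str
    interval: int = 1
    label: str = ""

    def __post_init__(self):
        if self.interval != 1:
            raise ConfigurationError("only an annual screening interval is supported")
        if self.stop_age != LIFETIME and self.stop_age < self.start_age:
            raise ConfigurationError(
                f"stop_age {self.stop_age} precedes start_age {self.start_age}"
            )
        if not self.label:
            object.__setattr__(self, "label", _default_label(self.start_age, self.stop_age))

    def active_at(self, age: float) -> bool:
        """True iff a screening round is offered at this (integer) age."""
        if age < self.start_age:
            return False
        return self.stop_age == LIFETIME or age < self.stop_age


#: Reference strategy: an empty window, never active.
NO_SCREENING = ScreeningScenario(start_age=0, stop_age=0, label=NO_SCREENING_LABEL)


def scenario_grid(start_ages=DEFAULT_START_AGES, stop_ages=DEFAULT_STOP_AGES,
                  include_reference: bool = True) -> list[ScreeningScenario]:
    """All (start, stop) combinations with stop > start, plus the reference.

    The default grid yields the six evaluated windows 50-60, 50-70, 50+,
    60-70, 60+ and 70+ together with the no-screening reference.
    """
    out: list[ScreeningScenario] = [NO_SCREENING] if include_reference else []
    for start in start_ages:
        for stop in stop_ages:
            if stop == LIFETIME or stop > start:
                out.append(ScreeningScenario(start_age=start, stop_age=stop))
    return out


@dataclass(frozen=True)
class DiagnosticCascade:
    """LDCT -> PET -> biopsy; zero combined false positives by assumption."""

    ldct_sensitivity: float
    false_positive_rate: float = 0.0
    confirmation_chain: tuple[str, ...] = ("PET", "biopsy")

    def __post_init__(self):
        if not 0.0 <= self.ldct_sensitivity <= 1.0:
            raise ConfigurationError("ldct_sensitivity must be in [0, 1]")
        if self.false_positive_rate != 0.0:
            raise ConfigurationError("the combined false-positive rate is fixed at zero")


@dataclass(frozen=True)
class EligibilityProfile:
    """Smoking history of a candidate participant."""

    age: float
    years_smoked: float
    cigarettes_per_day: float
    years_since_cessation: float = 0.0

    def __post_init__(self):
        for name in ("age", "years_smoked", "cigarettes_per_day", "years_since_cessation"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


def is_eligible(profile: EligibilityProfile, min_age: float = 50) -> bool:
    """Programme inclusion: > 30 smoking-years, >= 15 cigarettes/day,
    <= 10 years since cessation, and at least the programme start age."""
    return (
        profile.years_smoked > 30
        and profile.cigarettes_per_day >= 15
        and profile.years_since_cessation <= 10
        and profile.age >= min_age
    )


def screen_round(occupancy: np.ndarray, cascade: DiagnosticCascade):
    """Apply one screening round to undiagnosed prevalent cancer mass.

    Returns ``(detected, missed)`` with ``detected + missed`` equal to the
    input cell-by-cell.  The detected fraction equals the LDCT sensitivity
    (the confirmation chain adds no false positives); the missed remain
    undiagnosed and are screened again at the next round.
    """
    occupancy = np.asarray(occupancy, dtype=float)
    if occupancy.size and occupancy.min() < 0:
        raise ValueError("occupancy must be non-negative")
    detected = occupancy * cascade.ldct_sensitivity
    missed = occupancy - detected
    return detected, missed


def apply_stage_shift(cases: np.ndarray, rule: dict[str, float], stages,
                      early_stages=None) -> np.ndarray:
    """Counterfactual clinical-stage assignment for screen-detected cases.

    Screen detection at an early stage is assumed to have replaced a later
    clinical presentation; ``rule`` maps late-stage labels to weights
    (summing to 1) describing where each early-stage case would otherwise
    have surfaced.  ``cases`` is a per-stage vector (last axis = stage);
    mass in ``early_stages`` (default: every stage not named in the rule)
    is reassigned according to the rule, other mass is untouched.  Total
    mass is conserved.
    """
    stages = list(stages)
    cases = np.asarray(cases, dtype=float)
    if cases.shape[-1] != len(stages):
        raise ValueError("last axis of cases must match the stage labels")
    wsum = sum(rule.values())
    if abs(wsum - 1.0) > 1e-9:
        raise ValueError(f"counterfactual rule weights sum to {wsum}, expected 1")
    for s in rule:
        if s not in stages:
            raise KeyError(f"unknown target stage in rule: {s}")
    if early_stages is None:
        early_stages = [s for s in stages if s not in rule]
    early_idx = [stages.index(s) for s in early_stages]
    out = cases.copy()
    shifted = out[..., early_idx].sum(axis=-1)
    out[..., early_idx] = 0.0
    for s, w in rule.items():
        out[..., stages.index(s)] += shifted * w
    return out
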