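"""Health-state space of the lung-cancer natural-history Markov model.

The model distinguishes five histological types (SCLC plus the four NSCLC
types) and the seven TNM stage groups IA-IV.  Besides the five non-cancer
states (well, post-treatment, recurrence, and the two absorbing death
states) there is one cancer state per (histology, stage) pair, split into a
screen-detected and a clinically-detected variant, giving
``5 + 2 * H * S`` states (75 for the default configuration).

The public state ordering is stable and documented: non-cancer states
first, then cancer states histology-major, stage-minor, with the detection
variant varying fastest (screen-detected before clinically-detected).

Internally the cohort engine also tracks an *extended* chain in which the
"well" state is split into a healthy compartment and one preclinical
(undiagnosed cancer) compartment per histology; both are undiagnosed, so
their sum is reported as "well" in the public trace.  The extended chain is
a genuine linear time-varying Markov chain, which makes matrix-product
oracle checks possible.
"""

from __future__ import annotations

from dataclasses import dataclass

DEFAULT_HISTOLOGIES = (
    "SCLC",
    "adenocarcinoma",
    "squamous_cell",
    "large_cell",
    "other_NSCLC",
)
DEFAULT_STAGES = ("IA", "IB", "IIA", "IIB", "IIIA", "IIIB", "IV")

WELL = "well"
POST_TREATMENT = "post_treatment"
RECURRENCE = "recurrence"
DEATH_LUNG_CANCER = "death_lung_cancer"
DEATH_OTHER = "death_other"
NON_CANCER_STATES = (WELL, POST_TREATMENT, RECURRENCE, DEATH_LUNG_CANCER, DEATH_OTHER)
DEATH_STATES = (DEATH_LUNG_CANCER, DEATH_OTHER)
DETECTION_VARIANTS = ("screen", "clinical")

HEALTHY = "healthy"


class ConfigurationError(ValueError):
    """Raised for invalid state-space or parameter configuration."""


def cancer_state_label(histology: str, stage: str, variant: str) -> str:
    return f"{histology}|{stage}|{variant}"


@dataclass(frozen=True)
class StateSpace:
    """Labelled, ordered state space of the cohort model."""

    histologies: tuple[str, ...]
    stages: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.histologies or not self.stages:
            raise ConfigurationError("histologies and stages must be non-empty")
        for kind, labels in (("histology", self.histologies), ("stage", self.stages)):
            if len(set(labels)) != len(labels):
                raise ConfigurationError(f"duplicate {kind} labels: {labels}")
        overlap = set(self.histologies) & set(NON_CANCER_STATES)
        if overlap:
            raise ConfigurationError(f"histology labels clash with state names: {overlap}")

    @property
    def n_histologies(self) -> int:
        return len(self.histologies)

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @property
    def n_states(self) -> int:
        """Public state count: 5 non-cancer + 2 per (histology, stage)."""
        return len(NON_CANCER_STATES) + 2 * self.n_histologies * self.n_stages

    # -- public ordering ---------------------------------------------------
    @property
    def labels(self) -> tuple[str, ...]:
        cancer = [
            cancer_state_label(h, s, v)
            for h in self.histologies
            for s in self.stages
            for v in DETECTION_VARIANTS
        ]
        return NON_CANCER_STATES + tuple(cancer)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown state label: {label}") from None

    def cancer_index(self, i_hist: int, i_stage: int, i_variant: int) -> int:
        """Public index of cancer state (histology, stage, variant)."""
        return len(NON_CANCER_STATES) + (i_hist * self.n_stages + i_stage) * 2 + i_variant

    # -- extended ordering (internal chain) --------------------------------
    @property
    def extended_labels(self) -> tuple[str, ...]:
        pre = tuple(f"preclinical|{h}" for h in self.histologies)
        cancer = self.labels[len(NON_CANCER_STATES):]
        return (HEALTHY,) + pre + (POST_TREATMENT, RECURRENCE, DEATH_LUNG_CANCER, DEATH_OTHER) + cancer

    @property
    def n_extended(self) -> int:
        return 1 + self.n_histologies + 4 + 2 * self.n_histologies * self.n_stages

    @property
    def ext_cancer_offset(self) -> int:
        return 1 + self.n_histologies + 4

    def ext_index(self, label: str) -> int:
        try:
            return self.extended_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown extended state label: {label}") from None

    def ext_cancer_index(self, i_hist: int, i_stage: int, i_variant: int) -> int:
        return self.ext_cancer_offset + (i_hist * self.n_stages + i_stage) * 2 + i_variant


def build_state_space(
    n_histologies: int | None = None,
    stage_labels=None,
    histology_labels=None,
) -> StateSpace:
    """Build the labelled state space.

    ``n_histologies`` selects a prefix of the default histology labels (or
    generates generic labels beyond five); explicit ``histology_labels``
    override it.  ``stage_labels`` defaults to the seven TNM stage groups.
    """
    if histology_labels is not None:
        hist = tuple(histology_labels)
    else:
        n = 5 if n_histologies is None else int(n_histologies)
        if n < 1:
            raise ConfigurationError("n_histologies must be >= 1")
        if n <= len(DEFAULT_HISTOLOGIES):
            hist = DEFAULT_HISTOLOGIES[:n]
        else:
            extra = tuple(f"histology_{i}" for i in range(len(DEFAULT_HISTOLOGIES) + 1, n + 1))
            hist = DEFAULT_HISTOLOGIES + extra
    stages = tuple(stage_labels) if stage_labels is not None else DEFAULT_STAGES
    return StateSpace(histologies=hist, stages=stages)
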