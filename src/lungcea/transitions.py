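"""One-cycle transition matrices, validation and single-step propagation.

The cohort dynamics of one annual cycle factor into three row-stochastic
matrices applied left-to-right to a row occupancy vector over the extended
state space (healthy, preclinical-by-histology, post-treatment, recurrence,
the two death states, and the detected cancer states):

* ``S`` — the screening round: a sensitivity-sized fraction of each
  preclinical compartment moves to the screen-detected cancer states at the
  screen stage distribution (identity outside the screening window);
* ``D1`` — onset and presentation: well persons may die of other causes or
  develop (still undiagnosed) cancer; preclinical persons may die of other
  causes or present clinically at the clinical stage distribution;
* ``D2`` — disease outcomes: detected cancer states resolve lung-cancer
  death, other-cause death, cure and within-stage progression; the
  post-treatment and recurrence states resolve recurrence and death.

``build_transition_matrix`` returns the composed matrix ``S @ D1 @ D2``;
the fast engine in :mod:`lungcea.cohort` implements exactly the same maps
without materializing matrices, which the tests cross-check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import ParameterSet
from .states import (
    DEATH_LUNG_CANCER,
    DEATH_OTHER,
    DETECTION_VARIANTS,
    StateSpace,
)


def step_cohort(occupancy: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Propagate a row occupancy vector one cycle: ``occupancy @ matrix``."""
    occupancy = np.asarray(occupancy, dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if occupancy.shape[-1] != matrix.shape[0]:
        raise ValueError(
            f"occupancy length {occupancy.shape[-1]} != matrix dimension {matrix.shape[0]}"
        )
    return occupancy @ matrix


def validate_transitions(matrix: np.ndarray, labels=None, absorbing=(),
                         tol: float = 1e-9) -> list[str]:
    """Report every violated transition-matrix invariant (empty iff valid).

    Checks: entries in [0, 1], rows summing to 1 within ``tol``, and unit
    rows for declared absorbing states.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if labels is None:
        labels = [f"state_{i}" for i in range(n)]
    report: list[str] = []
    if matrix.shape != (n, n):
        return [f"matrix is not square: {matrix.shape}"]
    bad = np.argwhere((matrix < -tol) | (matrix > 1 + tol))
    for i, j in bad:
        report.append(f"entry {labels[i]} -> {labels[j]} = {matrix[i, j]:.6g} outside [0, 1]")
    sums = matrix.sum(axis=1)
    for i in np.flatnonzero(np.abs(sums - 1.0) > tol):
        report.append(f"row {labels[i]} sums to {sums[i]:.12f}, expected 1")
    for lab in absorbing:
        i = list(labels).index(lab)
        unit = np.zeros(n)
        unit[i] = 1.0
        if np.abs(matrix[i] - unit).max() > tol:
            report.append(f"absorbing state {lab} has a non-unit row")
    return report


# --------------------------------------------------------------- builders
def build_cycle_matrices(params: ParameterSet, age: int, screening_active: bool):
    """The three factor matrices (S, D1, D2) for one cycle at a given age."""
    sp = params.space
    H, S_n = sp.n_histologies, sp.n_stages
    n = sp.n_extended
    i_healthy = 0
    i_pre = np.arange(1, 1 + H)
    i_post = sp.ext_index("post_treatment")
    i_rec = sp.ext_index("recurrence")
    i_dlc = sp.ext_index(DEATH_LUNG_CANCER)
    i_doc = sp.ext_index(DEATH_OTHER)

    def cidx(h, s, v):
        return sp.ext_cancer_index(h, s, v)

    p_oc = params.mortality(age)
    p_on = params.onset_probability(age)

    S_mat = np.eye(n)
    if screening_active and params.sensitivity > 0:
        sens = params.sensitivity
        for h in range(H):
            S_mat[i_pre[h], i_pre[h]] = 1.0 - sens
            for s in range(S_n):
                S_mat[i_pre[h], cidx(h, s, 0)] = sens * params.stage_dist_screened[h, s]

    D1 = np.eye(n)
    D1[i_healthy, i_healthy] = (1.0 - p_oc) * (1.0 - p_on)
    D1[i_healthy, i_doc] = p_oc
    for h in range(H):
        D1[i_healthy, i_pre[h]] = (1.0 - p_oc) * p_on * params.histology_mix[h]
        pres = params.presentation_rate
        D1[i_pre[h], i_pre[h]] = (1.0 - p_oc) * (1.0 - pres)
        D1[i_pre[h], i_doc] = p_oc
        for s in range(S_n):
            D1[i_pre[h], cidx(h, s, 1)] = (1.0 - p_oc) * pres * params.stage_dist_clinical[h, s]

    D2 = np.eye(n)
    for h in range(H):
        for s in range(S_n):
            p_lc = params.p_lc_death[h, s]
            cure = params.p_cure[h, s]
            prog = params.progression_rate if s < S_n - 1 else 0.0
            surv = (1.0 - p_lc) * (1.0 - p_oc)
            for v in range(2):
                i = cidx(h, s, v)
                D2[i, i] = surv * (1.0 - cure) * (1.0 - prog)
                D2[i, i_dlc] = p_lc
                D2[i, i_doc] = (1.0 - p_lc) * p_oc
                D2[i, i_post] = surv * cure
                if prog:
                    D2[i, cidx(h, s + 1, v)] = surv * (1.0 - cure) * prog
    D2[i_post, i_post] = (1.0 - p_oc) * (1.0 - params.recurrence_rate)
    D2[i_post, i_doc] = p_oc
    D2[i_post, i_rec] = (1.0 - p_oc) * params.recurrence_rate
    p_rlc = params.recurrence_lc_mortality
    D2[i_rec, i_rec] = (1.0 - p_rlc) * (1.0 - p_oc)
    D2[i_rec, i_dlc] = p_rlc
    D2[i_rec, i_doc] = (1.0 - p_rlc) * p_oc
    return S_mat, D1, D2


def build_transition_matrix(params: ParameterSet, age: int,
                            screening_active: bool = False) -> np.ndarray:
    S_mat, D1, D2 = build_cycle_matrices(params, age, screening_active)
    return S_mat @ D1 @ D2


def transition_matrices(params: ParameterSet, scenario, start_age: int,
                        horizon: int) -> list[np.ndarray]:
    """Per-cycle composed matrices for a cohort entering at ``start_age``."""
    out = []
    for t in range(horizon):
        age = start_age + t
        active = scenario is not None and scenario.active_at(age)
        out.append(build_transition_matrix(params, age, active))
    return out


def validate_parameter_transitions(params: ParameterSet, ages=(50, 60, 70, 80, 90, 99)):
    """Validate the composed matrices at several ages, screening on and off."""
    labels = params.space.extended_labels
    report: list[str] = []
    for age in ages:
        for active in (False, True):
            issues = validate_transitions(
                build_transition_matrix(params, age, active), labels,
                absorbing=(DEATH_LUNG_CANCER, DEATH_OTHER),
            )
            report += [f"age {age}, screening={active}: {msg}" for msg in issues]
    return report


# ------------------------------------------------------ long-format tables
LONG_COLUMNS = ["from_state", "to_state", "age_band", "probability"]


def matrix_to_long(matrix: np.ndarray, labels, age_band="all") -> pd.DataFrame:
    """Sparse long-format view of a transition matrix.

    Off-diagonal non-zero entries only; unlisted pairs are zero and the
    diagonal is the remainder that makes each row sum to 1.
    """
    matrix = np.asarray(matrix, dtype=float)
    rows = []
    for i, j in np.argwhere(matrix != 0):
        if i != j:
            rows.append((labels[i], labels[j], age_band, matrix[i, j]))
    return pd.DataFrame(rows, columns=LONG_COLUMNS)


def matrix_from_long(frame: pd.DataFrame, labels) -> np.ndarray:
    """Rebuild a matrix from long format under the documented convention:
    unlisted pairs are 0 and the diagonal is computed as the row remainder."""
    labels = list(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    m = np.zeros((n, n))
    for row in frame.itertuples(index=False):
        m[idx[row.from_state], idx[row.to_state]] = float(row.probability)
    np.fill_diagonal(m, 0.0)
    np.fill_diagonal(m, 1.0 - m.sum(axis=1))
    return m


def disease_grid_to_long(params: ParameterSet) -> pd.DataFrame:
    """Age-invariant disease transitions (cancer grid, post-treatment,
    recurrence) in the long CSV dialect the readers consume."""
    sp = params.space
    rows = []
    for h_i, h in enumerate(sp.histologies):
        for s_i, s in enumerate(sp.stages):
            for v in DETECTION_VARIANTS:
                frm = f"{h}|{s}|{v}"
                rows.append((frm, DEATH_LUNG_CANCER, "all", params.p_lc_death[h_i, s_i]))
                rows.append((frm, "post_treatment", "all", params.p_cure[h_i, s_i]))
                if s_i < sp.n_stages - 1:
                    rows.append((frm, f"{h}|{sp.stages[s_i + 1]}|{v}", "all",
                                 params.progression_rate))
    rows.append(("post_treatment", "recurrence", "all", params.recurrence_rate))
    rows.append(("recurrence", DEATH_LUNG_CANCER, "all", params.recurrence_lc_mortality))
    return pd.DataFrame(rows, columns=LONG_COLUMNS)


def disease_grid_from_long(frame: pd.DataFrame, space: StateSpace) -> dict:
    """Parse the long-format disease grid back into parameter arrays."""
    H, S = space.n_histologies, space.n_stages
    p_lc = np.full((H, S), np.nan)
    p_cure = np.full((H, S), np.nan)
    prog: list[float] = []
    rec_rate = rec_lc = None
    for row in frame.itertuples(index=False):
        frm, to, p = row.from_state, row.to_state, float(row.probability)
        if frm == "post_treatment" and to == "recurrence":
            rec_rate = p
            continue
        if frm == "recurrence" and to == DEATH_LUNG_CANCER:
            rec_lc = p
            continue
        parts = frm.split("|")
        if len(parts) != 3:
            raise ValueError(f"unrecognized from_state: {frm}")
        h_i = space.histologies.index(parts[0])
        s_i = space.stages.index(parts[1])
        if to == DEATH_LUNG_CANCER:
            p_lc[h_i, s_i] = p
        elif to == "post_treatment":
            p_cure[h_i, s_i] = p
        elif "|" in to:
            prog.append(p)
        else:
            raise ValueError(f"unrecognized to_state: {to}")
    if np.isnan(p_lc).any() or np.isnan(p_cure).any():
        raise ValueError("disease grid is missing lung-cancer death or cure entries")
    if rec_rate is None or rec_lc is None:
        raise ValueError("disease grid is missing recurrence entries")
    prog_rate = prog[0] if prog else 0.0
    if prog and (max(prog) - min(prog)) > 1e-12:
        raise ValueError("progression probabilities are not uniform across states")
    return {
        "p_lc_death": p_lc,
        "p_cure": p_cure,
        "progression_rate": prog_rate,
        "recurrence_rate": rec_rate,
        "recurrence_lc_mortality": rec_lc,
    }
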