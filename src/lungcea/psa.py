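"""Probabilistic sensitivity analysis: sampling, CE plane, CEAC, CEAF.

Parameter uncertainty is expressed per parameter as a base value with a
(lo, hi) range, interpreted as a central 95% interval.  Probabilities and
utilities draw from moment-matched beta distributions, costs from gamma
distributions; the distribution mean always equals the base value.  Each
Monte Carlo draw perturbs a copy of the base parameter set (stage
distributions are renormalized proportionally afterwards), and all
scenarios are evaluated under the same draw (common random numbers), so
the acceptability curves compare strategies coherently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ParameterError, ParameterSet
from .pipeline import evaluate_scenarios

DEFAULT_WTP_GRID = np.arange(0.0, 50_001.0, 100.0)


@dataclass(frozen=True)
class UncertaintyEntry:
    parameter_id: str
    base: float
    family: str                 # "beta" | "gamma"
    lo: float
    hi: float

    def __post_init__(self):
        if self.family not in ("beta", "gamma"):
            raise ValueError(f"unknown family {self.family!r}")
        if not self.lo <= self.base <= self.hi:
            raise ValueError(f"{self.parameter_id}: base outside [lo, hi]")
        if self.family == "beta" and not (0.0 <= self.lo and self.hi <= 1.0):
            raise ValueError(f"{self.parameter_id}: beta range outside [0, 1]")
        if self.family == "gamma" and self.lo < 0:
            raise ValueError(f"{self.parameter_id}: gamma range must be non-negative")


@dataclass
class UncertaintySpec:
    """Ordered collection of per-parameter uncertainty entries."""

    entries: dict[str, UncertaintyEntry] = field(default_factory=dict)

    def add(self, entry: UncertaintyEntry) -> None:
        self.entries[entry.parameter_id] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.parameter_id, e.base, e.family, e.lo, e.hi) for e in self],
            columns=["parameter_id", "base", "family", "lo", "hi"],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "UncertaintySpec":
        spec = cls()
        for row in frame.itertuples(index=False):
            spec.add(UncertaintyEntry(row.parameter_id, float(row.base), row.family,
                                      float(row.lo), float(row.hi)))
        return spec


def fit_distribution(base: float, lo: float, hi: float, family: str) -> dict:
    """Moment-matched hyperparameters with mean equal to ``base``.

    The (lo, hi) range is read as a central 95% interval, so the implied
    standard deviation is ``(hi - lo) / (2 * 1.96)``.  A zero-width range
    yields a point mass.  For the beta family the variance is capped just
    below the feasible maximum ``m (1 - m)``.
    """
    if family not in ("beta", "gamma"):
        raise ValueError(f"unknown family {family!r}")
    if hi < lo:
        raise ValueError("hi < lo")
    sd = (hi - lo) / (2.0 * 1.96)
    if sd == 0.0:
        return {"family": "point", "value": base}
    if family == "beta":
        if not 0.0 < base < 1.0:
            if base in (0.0, 1.0):
                return {"family": "point", "value": base}
            raise ValueError(f"beta base {base} outside [0, 1]")
        var = min(sd * sd, 0.99 * base * (1.0 - base))
        k = base * (1.0 - base) / var - 1.0
        return {"family": "beta", "a": base * k, "b": (1.0 - base) * k}
    if base <= 0.0:
        return {"family": "point", "value": base}
    var = sd * sd
    return {"family": "gamma", "shape": base * base / var, "scale": var / base}


def sample_value(hyper: dict, rng: np.random.Generator) -> float:
    if hyper["family"] == "point":
        return hyper["value"]
    if hyper["family"] == "beta":
        return float(rng.beta(hyper["a"], hyper["b"]))
    return float(rng.gamma(hyper["shape"], hyper["scale"]))


def sample_parameter_set(base: ParameterSet, spec: UncertaintySpec,
                         rng: np.random.Generator,
                         max_redraws: int = 100) -> tuple[ParameterSet, int]:
    """One valid random parameter set; returns (params, redraw count).

    Draws every entry of ``spec``, renormalizes the stage-distribution rows
    proportionally if any of their cells were actually perturbed, and
    redraws whole sets that fail validation (up to ``max_redraws``).  With
    every distribution degenerate the base values are reproduced exactly.
    """
    hypers = {e.parameter_id: fit_distribution(e.base, e.lo, e.hi, e.family)
              for e in spec}
    perturbs_dist = any(
        pid.startswith("stage_dist.") and h["family"] != "point"
        for pid, h in hypers.items()
    )
    for redraw in range(max_redraws + 1):
        ps = base.copy()
        for pid, hyper in hypers.items():
            ps.set_param(pid, sample_value(hyper, rng))
        if perturbs_dist:
            ps.stage_dist_clinical /= ps.stage_dist_clinical.sum(axis=1, keepdims=True)
            ps.stage_dist_screened /= ps.stage_dist_screened.sum(axis=1, keepdims=True)
        if not ps.validate():
            return ps, redraw
    raise ParameterError([f"no valid draw after {max_redraws} redraws"])


@dataclass
class PSAResult:
    """Per-draw (cost, QALYs) for every scenario under common draws."""

    scenario_labels: list[str]
    costs: np.ndarray              # (n_draws, n_scenarios)
    qalys: np.ndarray              # (n_draws, n_scenarios)
    seed: int
    redraws: int = 0

    @property
    def n_draws(self) -> int:
        return self.costs.shape[0]

    def frame(self) -> pd.DataFrame:
        rows = []
        for d in range(self.n_draws):
            for j, lab in enumerate(self.scenario_labels):
                rows.append((d, lab, self.costs[d, j], self.qalys[d, j]))
        return pd.DataFrame(rows, columns=["draw", "scenario", "cost", "qalys"])


def run_psa(base: ParameterSet, spec: UncertaintySpec, scenarios, population,
            n_draws: int, seed: int, horizon_age: int = 100) -> PSAResult:
    """Monte Carlo propagation of parameter uncertainty through the model.

    Draw ``d`` always uses the seed stream ``SeedSequence(seed, spawn_key=(d,))``,
    so results are independent of evaluation order and resumable by draw
    index.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    labels = [sc.label if sc is not None else "no screening" for sc in scenarios]
    costs = np.empty((n_draws, len(labels)))
    qalys = np.empty((n_draws, len(labels)))
    redraws = 0
    for d in range(n_draws):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(d,)))
        ps, r = sample_parameter_set(base, spec, rng)
        redraws += r
        ev = evaluate_scenarios(ps, scenarios, population, horizon_age)
        for j, res in enumerate(ev.results):
            costs[d, j] = res.cost
            qalys[d, j] = res.qalys
    return PSAResult(labels, costs, qalys, seed, redraws)


def nmb(wtp, cost, qalys):
    """Net monetary benefit: ``wtp * qalys - cost`` (vectorized)."""
    return np.asarray(wtp) * np.asarray(qalys) - np.asarray(cost)


def ceac(result: PSAResult, wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    For each willingness-to-pay value, the fraction of draws in which each
    scenario attains the maximum net monetary benefit; exact ties are split
    equally, so the probabilities sum to 1 at every WTP.
    """
    wtp_grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    probs = np.empty((wtp_grid.size, len(result.scenario_labels)))
    for i, w in enumerate(wtp_grid):
        benefit = nmb(w, result.costs, result.qalys)
        winners = benefit == benefit.max(axis=1, keepdims=True)
        probs[i] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    out = pd.DataFrame(probs, columns=result.scenario_labels)
    out.insert(0, "wtp", wtp_grid)
    return out


def ceaf(result: PSAResult, wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability frontier.

    At each WTP the scenario with the highest *expected* net monetary
    benefit is selected and reported with its CEAC probability (ties break
    toward the lower-cost scenario).
    """
    wtp_grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    curves = ceac(result, wtp_grid)
    mean_cost = result.costs.mean(axis=0)
    mean_qalys = result.qalys.mean(axis=0)
    cost_order = np.argsort(mean_cost, kind="stable")
    rows = []
    for i, w in enumerate(wtp_grid):
        mean_benefit = nmb(w, mean_cost, mean_qalys)
        best = cost_order[np.argmax(mean_benefit[cost_order])]
        lab = result.scenario_labels[best]
        rows.append((w, lab, curves.iloc[i][lab]))
    return pd.DataFrame(rows, columns=["wtp", "scenario", "probability"])


def ceaf_switch_points(frontier: pd.DataFrame) -> pd.DataFrame:
    """WTP values at which the expected-NMB-optimal scenario changes."""
    rows = []
    prev = None
    for row in frontier.itertuples(index=False):
        if prev is not None and row.scenario != prev:
            rows.append((row.wtp, prev, row.scenario))
        prev = row.scenario
    return pd.DataFrame(rows, columns=["wtp", "from_scenario", "to_scenario"])
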