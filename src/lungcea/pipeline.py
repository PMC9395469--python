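"""Scenario evaluation: pooled multi-age cohorts to discounted totals.

Each start-age group (10,000 persons by default, ten groups, 100,000 in
total) is simulated as its own closed cohort under a common calendar
clock; discounted costs and QALYs are summed across groups, so the pooled
totals are directly "per 100,000 individuals" under the default
population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import ScenarioResult, budget_impact
from .cohort import DEFAULT_HORIZON_AGE, CohortResult, run_cohort
from .economics import accumulate_costs, accumulate_qalys, cost_streams
from .params import ParameterSet


def _population_frame(population) -> pd.DataFrame:
    if isinstance(population, pd.DataFrame):
        frame = population
    else:
        frame = pd.DataFrame(list(population), columns=["start_age", "count"])
    if not {"start_age", "count"} <= set(frame.columns):
        raise ValueError("population needs 'start_age' and 'count' columns")
    return frame


@dataclass
class ScenarioEvaluation:
    result: ScenarioResult
    cost_stream: np.ndarray            # pooled, undiscounted, per calendar cycle
    group_results: list[CohortResult]


def run_scenario(params: ParameterSet, scenario, population,
                 horizon_age: int = DEFAULT_HORIZON_AGE) -> ScenarioEvaluation:
    """Evaluate one strategy over the pooled age-group population."""
    frame = _population_frame(population)
    costs = params.cost_table()
    utilities = params.utility_table()
    spec = params.discount_spec()
    total_cost = 0.0
    total_qalys = 0.0
    group_results: list[CohortResult] = []
    streams: list[np.ndarray] = []
    for row in frame.itertuples(index=False):
        res = run_cohort(params, scenario, start_age=int(row.start_age),
                         cohort_size=float(row.count), horizon_age=horizon_age)
        total_cost += accumulate_costs(res.trace, res.events, costs, spec)
        total_qalys += accumulate_qalys(res.trace, utilities, spec)
        group_streams = cost_streams(res.trace, res.events, costs)
        streams.append(sum(group_streams.values()))
        group_results.append(res)
    length = max(s.size for s in streams)
    pooled = np.zeros(length)
    for s in streams:
        pooled[:s.size] += s
    label = scenario.label if scenario is not None else "no screening"
    return ScenarioEvaluation(ScenarioResult(label, total_cost, total_qalys),
                              pooled, group_results)


@dataclass
class Evaluation:
    """Results of evaluating a scenario set over one population."""

    results: list[ScenarioResult]
    streams: dict[str, np.ndarray]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.label, r.cost, r.qalys) for r in self.results],
            columns=["scenario", "cost", "qalys"],
        )

    def budget_impact_frame(self, reference_label: str = "no screening") -> pd.DataFrame:
        ref = self.streams[reference_label]
        data = {"cycle": np.arange(ref.size)}
        for label, stream in self.streams.items():
            if label != reference_label:
                data[label] = budget_impact(stream, ref)
        return pd.DataFrame(data)


def evaluate_scenarios(params: ParameterSet, scenarios, population,
                       horizon_age: int = DEFAULT_HORIZON_AGE) -> Evaluation:
    results = []
    streams = {}
    for sc in scenarios:
        ev = run_scenario(params, sc, population, horizon_age)
        results.append(ev.result)
        streams[ev.result.label] = ev.cost_stream
    return Evaluation(results, streams)
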