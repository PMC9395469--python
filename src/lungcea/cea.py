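"""Incremental cost-effectiveness analysis and the efficiency frontier.

Scenarios are sorted by increasing total discounted cost.  Strictly
dominated strategies (at least as expensive, no more effective than some
alternative) are removed first; extended dominance then iteratively
removes any strategy whose sequential ICER (versus the next least
expensive surviving strategy) is not smaller than the next one along,
until the sequential ICERs are strictly increasing.  The survivors form
the efficiency frontier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ON_FRONTIER = "on-frontier"
STRICTLY_DOMINATED = "strictly-dominated"
EXTENDED_DOMINATED = "extended-dominated"


@dataclass(frozen=True)
class ScenarioResult:
    """Total discounted cost (EUR) and QALYs of one strategy, per cohort."""

    label: str
    cost: float
    qalys: float

    def __post_init__(self):
        if self.cost < 0 or self.qalys < 0:
            raise ValueError("cost and QALYs must be >= 0")


@dataclass
class FrontierEntry:
    label: str
    cost: float
    qalys: float
    status: str
    icer: float | None = None      # sequential, on-frontier entries after the cheapest
    cer: float | None = None       # vs the common reference, filled by table1_report


@dataclass(frozen=True)
class ICERResult:
    value: float | None
    flag: str                      # "ratio" | "dominant" | "dominated" | "equivalent"


def incremental(a: ScenarioResult, ref: ScenarioResult) -> tuple[float, float]:
    """(delta cost, delta QALYs) of ``a`` versus ``ref``; signs preserved."""
    return a.cost - ref.cost, a.qalys - ref.qalys


def icer(delta_cost: float, delta_qalys: float) -> ICERResult:
    """Incremental cost-effectiveness ratio with dominance flags.

    Returns the ratio when QALYs are gained; flags "dominant" when QALYs
    are gained at no extra cost, "dominated" when QALYs are lost at no
    saving, and guards the undefined ratio at zero QALY difference.
    """
    if delta_qalys > 0:
        value = delta_cost / delta_qalys
        return ICERResult(value, "dominant" if delta_cost <= 0 else "ratio")
    if delta_qalys < 0:
        if delta_cost >= 0:
            return ICERResult(None, "dominated")
        return ICERResult(delta_cost / delta_qalys, "ratio")
    if delta_cost > 0:
        return ICERResult(None, "dominated")
    if delta_cost < 0:
        return ICERResult(None, "dominant")
    return ICERResult(None, "equivalent")


def efficiency_frontier(results: list[ScenarioResult]) -> list[FrontierEntry]:
    """Label every scenario on-frontier, strictly- or extended-dominated.

    Ties: equal cost keeps the higher-QALY scenario; equal cost and QALYs
    keeps the first in label order and warns.
    """
    if not results:
        raise ValueError("at least one scenario result is required")
    order = sorted(results, key=lambda r: (r.cost, -r.qalys, r.label))
    entries = {r.label: FrontierEntry(r.label, r.cost, r.qalys, ON_FRONTIER) for r in order}

    candidates: list[ScenarioResult] = []
    best_q = -np.inf
    for r in order:
        if candidates and r.qalys <= best_q:
            entries[r.label].status = STRICTLY_DOMINATED
            prev = candidates[-1]
            if r.cost == prev.cost and r.qalys == prev.qalys:
                warnings.warn(
                    f"scenarios {prev.label!r} and {r.label!r} are tied in cost and QALYs;"
                    f" keeping {prev.label!r}", stacklevel=2)
            continue
        candidates.append(r)
        best_q = r.qalys

    # extended dominance: prune until sequential ICERs strictly increase
    changed = True
    while changed and len(candidates) > 2:
        changed = False
        icers = [
            (candidates[i + 1].cost - candidates[i].cost)
            / (candidates[i + 1].qalys - candidates[i].qalys)
            for i in range(len(candidates) - 1)
        ]
        for i in range(len(icers) - 1):
            if icers[i] >= icers[i + 1]:
                entries[candidates[i + 1].label].status = EXTENDED_DOMINATED
                del candidates[i + 1]
                changed = True
                break

    for i, r in enumerate(candidates):
        if i > 0:
            prev = candidates[i - 1]
            entries[r.label].icer = (r.cost - prev.cost) / (r.qalys - prev.qalys)
    return [entries[r.label] for r in order]


def cer_vs_reference(results: list[ScenarioResult], reference) -> pd.DataFrame:
    """Cost-effectiveness ratios of every scenario versus a common reference.

    ``reference`` is a label or a ScenarioResult contained in ``results``.
    The reference itself is excluded from the output; a zero QALY
    difference is flagged instead of producing a ratio.
    """
    if isinstance(reference, str):
        matches = [r for r in results if r.label == reference]
        if not matches:
            raise ValueError(f"reference {reference!r} not among the results")
        reference = matches[0]
    elif reference not in results:
        raise ValueError("reference must be among the results")
    rows = []
    for r in results:
        if r.label == reference.label:
            continue
        dc, dq = incremental(r, reference)
        res = icer(dc, dq)
        rows.append((r.label, dc, dq, res.value, res.flag))
    return pd.DataFrame(rows, columns=["label", "delta_cost", "delta_qalys", "cer", "flag"])


def budget_impact(cost_stream: np.ndarray, reference_stream: np.ndarray) -> np.ndarray:
    """Annual undiscounted incremental cost stream versus the reference.

    Sums to the undiscounted total incremental cost.
    """
    cost_stream = np.asarray(cost_stream, dtype=float)
    reference_stream = np.asarray(reference_stream, dtype=float)
    if cost_stream.shape != reference_stream.shape:
        raise ValueError(
            f"horizon mismatch: {cost_stream.shape} vs {reference_stream.shape}"
        )
    return cost_stream - reference_stream


def table1_report(results: list[ScenarioResult], reference_label: str) -> pd.DataFrame:
    """Per-scenario report sorted by cost: totals, dominance, sequential
    ICERs (frontier rows only), and vs-reference columns for all rows.

    Extended-dominated rows carry ``*`` in the ``note`` column.
    """
    entries = efficiency_frontier(results)
    cers = cer_vs_reference(results, reference_label).set_index("label")
    rows = []
    for e in entries:
        vs = cers.loc[e.label] if e.label in cers.index else None
        rows.append({
            "scenario": e.label,
            "note": "*" if e.status == EXTENDED_DOMINATED else "",
            "cost": e.cost,
            "qalys": e.qalys,
            "icer": e.icer,
            "status": e.status,
            "cost_vs_reference": None if vs is None else vs["delta_cost"],
            "qalys_vs_reference": None if vs is None else vs["delta_qalys"],
            "cer": None if vs is None else vs["cer"],
        })
    return pd.DataFrame(rows)


def format_table1(report: pd.DataFrame, currency: str = "EUR") -> str:
    out = report.copy()
    for col in ("cost", "icer", "cost_vs_reference", "cer"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:,.0f}")
    for col in ("qalys", "qalys_vs_reference"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:,.1f}")
    text = out.to_string(index=False)
    return f"{text}\n* extended-dominated scenario; monetary amounts in {currency}\n"
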