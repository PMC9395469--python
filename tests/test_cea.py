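"""ICER arithmetic, dominance, efficiency frontier, budget impact, report."""

import numpy as np
import pandas as pd
import pytest

from lungcea.cea import (EXTENDED_DOMINATED, ON_FRONTIER, STRICTLY_DOMINATED,
                         ScenarioResult, budget_impact, cer_vs_reference,
                         efficiency_frontier, icer, incremental, table1_report)
from lungcea.reference import (PRINTED_CERS, PRINTED_COST_VS_NO_SCREENING,
                               PRINTED_EXTENDED_DOMINATED, table1_results)


def brute_force_labels(results):
    """Oracle: strict dominance by pairwise comparison; extended dominance by
    testing every point against the segment of every cheaper/dearer pair."""
    status = {}
    for r in results:
        dominated = any(
            o is not r and o.cost <= r.cost and o.qalys >= r.qalys
            and (o.cost < r.cost or o.qalys > r.qalys or o.label < r.label)
            for o in results
        )
        status[r.label] = STRICTLY_DOMINATED if dominated else ON_FRONTIER
    alive = [r for r in results if status[r.label] == ON_FRONTIER]
    for p in alive:
        for a in alive:
            for b in alive:
                if a.cost < p.cost < b.cost:
                    frac = (p.cost - a.cost) / (b.cost - a.cost)
                    if p.qalys < a.qalys + frac * (b.qalys - a.qalys):
                        status[p.label] = EXTENDED_DOMINATED
    return status


class TestIncrementalArithmetic:
    def test_printed_cost_deltas(self):
        results = {r.label: r for r in table1_results()}
        ref = results["no screening"]
        dc, dq = incremental(results["50-60"], ref)
        assert dc == 4_668_542.0
        dc, dq = incremental(results["70+"], ref)
        assert round(dq, 1) == 87.8

    def test_self_difference_is_zero(self):
        r = ScenarioResult("x", 100.0, 10.0)
        assert incremental(r, r) == (0.0, 0.0)


class TestICER:
    def test_dominant_boundary(self):
        res = icer(0.0, 10.0)
        assert res.value == 0.0 and res.flag == "dominant"

    def test_printed_ratio(self):
        res = icer(4_668_542.0, 331.2)
        assert res.flag == "ratio"
        assert res.value == pytest.approx(14_096, abs=1.0)

    def test_sign_case_oracle(self):
        """Flags match the sign table and ratios match direct division."""
        rng = np.random.default_rng(5)
        for dc, dq in rng.normal(0, 1e5, size=(200, 2)):
            res = icer(dc, dq)
            if dq > 0:
                assert res.value == dc / dq
                assert res.flag == ("dominant" if dc <= 0 else "ratio")
            elif dq < 0 and dc >= 0:
                assert res.flag == "dominated" and res.value is None
            elif dq < 0:
                assert res.flag == "ratio" and res.value == dc / dq
        assert icer(5.0, 0.0).flag == "dominated"
        assert icer(-5.0, 0.0).flag == "dominant"
        assert icer(0.0, 0.0).flag == "equivalent"


class TestFrontier:
    def test_published_pairs_reproduce_published_labels(self):
        entries = {e.label: e for e in efficiency_frontier(table1_results())}
        dominated = {lab for lab, e in entries.items() if e.status == EXTENDED_DOMINATED}
        assert dominated == set(PRINTED_EXTENDED_DOMINATED)
        frontier = [lab for lab, e in entries.items() if e.status == ON_FRONTIER]
        assert set(frontier) == {"no screening", "50-60", "50-70", "50+"}

    def test_single_scenario(self):
        entries = efficiency_frontier([ScenarioResult("only", 10.0, 1.0)])
        assert entries[0].status == ON_FRONTIER and entries[0].icer is None

    def test_randomized_sets_match_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            n = rng.integers(2, 8)
            results = [
                ScenarioResult(f"s{i}", float(rng.uniform(0, 1e6)),
                               float(rng.uniform(0, 1e3)))
                for i in range(n)
            ]
            got = {e.label: e.status for e in efficiency_frontier(results)}
            assert got == brute_force_labels(results)

    def test_sequential_icers_strictly_increase(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            results = [ScenarioResult(f"s{i}", float(rng.uniform(0, 1e6)),
                                      float(rng.uniform(0, 1e3))) for i in range(6)]
            icers = [e.icer for e in efficiency_frontier(results) if e.icer is not None]
            assert all(a < b for a, b in zip(icers, icers[1:]))

    def test_invariant_to_order_and_currency_rescale(self):
        results = table1_results()
        shuffled = list(reversed(results))
        base = {e.label: e.status for e in efficiency_frontier(results)}
        assert {e.label: e.status for e in efficiency_frontier(shuffled)} == base
        scaled = [ScenarioResult(r.label, r.cost * 1.37, r.qalys) for r in results]
        assert {e.label: e.status for e in efficiency_frontier(scaled)} == base

    def test_removing_extended_dominated_point_is_stable(self):
        results = table1_results()
        base = {e.label: e.status for e in efficiency_frontier(results)}
        for drop in PRINTED_EXTENDED_DOMINATED:
            sub = [r for r in results if r.label != drop]
            got = {e.label: e.status for e in efficiency_frontier(sub)}
            for lab, status in got.items():
                assert status == base[lab]

    def test_equal_cost_tie_breaking(self):
        a = ScenarioResult("a", 100.0, 5.0)
        b = ScenarioResult("b", 100.0, 7.0)
        entries = {e.label: e.status for e in efficiency_frontier([a, b])}
        assert entries == {"a": STRICTLY_DOMINATED, "b": ON_FRONTIER}
        twin = ScenarioResult("twin", 100.0, 7.0)
        with pytest.warns(UserWarning, match="tied"):
            entries = {e.label: e.status for e in efficiency_frontier([b, twin])}
        assert entries["b"] == ON_FRONTIER and entries["twin"] == STRICTLY_DOMINATED


class TestCER:
    def test_printed_cers_within_rounding(self):
        frame = cer_vs_reference(table1_results(), "no screening").set_index("label")
        for lab, printed in PRINTED_CERS.items():
            # printed CERs divide unrounded QALY totals; printed totals get within 25 EUR
            assert frame.loc[lab, "cer"] == pytest.approx(printed, abs=25)
        for lab, printed in PRINTED_COST_VS_NO_SCREENING.items():
            assert frame.loc[lab, "delta_cost"] == printed

    def test_composition_matches_incremental_plus_icer(self):
        rng = np.random.default_rng(3)
        results = [ScenarioResult(f"s{i}", float(rng.uniform(1, 1e6)),
                                  float(rng.uniform(1, 1e3))) for i in range(5)]
        frame = cer_vs_reference(results, results[0]).set_index("label")
        for r in results[1:]:
            dc, dq = incremental(r, results[0])
            expected = icer(dc, dq).value
            got = frame.loc[r.label, "cer"]
            assert (np.isnan(got) if expected is None else got == expected)
        assert results[0].label not in frame.index

    def test_zero_qaly_difference_flagged(self):
        a = ScenarioResult("ref", 10.0, 5.0)
        b = ScenarioResult("b", 20.0, 5.0)
        frame = cer_vs_reference([a, b], "ref")
        assert frame.iloc[0]["flag"] == "dominated"
        assert pd.isna(frame.iloc[0]["cer"])


class TestBudgetImpact:
    def test_difference_and_total(self):
        a = np.array([0.0, 100.0, 50.0])
        ref = np.array([0.0, 40.0, 10.0])
        stream = budget_impact(a, ref)
        np.testing.assert_array_equal(stream, [0.0, 60.0, 40.0])
        assert stream.sum() == (a.sum() - ref.sum())

    def test_horizon_mismatch(self):
        with pytest.raises(ValueError, match="horizon"):
            budget_impact(np.zeros(3), np.zeros(4))

    def test_identical_streams_are_all_zero(self):
        s = np.arange(5.0)
        assert not budget_impact(s, s).any()


class TestReport:
    def test_asterisks_on_extended_dominated_rows(self):
        report = table1_report(table1_results(), "no screening")
        starred = set(report.loc[report["note"] == "*", "scenario"])
        assert starred == set(PRINTED_EXTENDED_DOMINATED)
        assert list(report["cost"]) == sorted(report["cost"])
        # sequential ICERs only on frontier rows after the cheapest
        assert report.loc[report["note"] == "*", "icer"].isna().all()

    def test_single_scenario_report(self):
        report = table1_report([ScenarioResult("only", 5.0, 1.0)], "only")
        assert len(report) == 1 and pd.isna(report.iloc[0]["icer"])

    def test_columns_recompute_from_raw_results(self):
        results = table1_results()
        report = table1_report(results, "no screening").set_index("scenario")
        ref = next(r for r in results if r.label == "no screening")
        for r in results:
            if r.label == "no screening":
                continue
            dc, dq = incremental(r, ref)
            assert report.loc[r.label, "cost_vs_reference"] == dc
            assert report.loc[r.label, "qalys_vs_reference"] == dq
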