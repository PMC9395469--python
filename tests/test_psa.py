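"""Distribution fitting, parameter sampling, CEAC/CEAF behaviour."""

import numpy as np
import pytest

from lungcea.pipeline import evaluate_scenarios
from lungcea.psa import (PSAResult, UncertaintyEntry, UncertaintySpec, ceac,
                         ceaf, ceaf_switch_points, fit_distribution, nmb,
                         run_psa, sample_parameter_set, sample_value)
from lungcea.synthetic import generate_uncertainty_spec


class TestFitDistribution:
    def test_symmetric_beta_has_equal_shapes(self):
        hyper = fit_distribution(0.5, 0.3, 0.7, "beta")
        assert hyper["a"] == pytest.approx(hyper["b"], rel=1e-12)

    def test_gamma_sampling_mean_matches_base(self):
        hyper = fit_distribution(1000.0, 900.0, 1100.0, "gamma")
        rng = np.random.default_rng(0)
        draws = rng.gamma(hyper["shape"], hyper["scale"], size=100_000)
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 1000.0) < 3 * se

    def test_beta_mean_round_trip(self):
        for base in (0.1, 0.5, 0.9):
            hyper = fit_distribution(base, base * 0.9, min(base * 1.1, 1.0), "beta")
            mean = hyper["a"] / (hyper["a"] + hyper["b"])
            assert mean == pytest.approx(base, abs=1e-6)

    def test_degenerate_range_is_point_mass(self):
        hyper = fit_distribution(0.4, 0.4, 0.4, "beta")
        assert hyper == {"family": "point", "value": 0.4}
        rng = np.random.default_rng(1)
        assert sample_value(hyper, rng) == 0.4

    def test_out_of_support_base_rejected(self):
        with pytest.raises(ValueError):
            fit_distribution(1.5, 1.4, 1.6, "beta")


class TestSampling:
    def test_empty_spec_returns_base_unchanged(self, params):
        rng = np.random.default_rng(0)
        drawn, redraws = sample_parameter_set(params, UncertaintySpec(), rng)
        assert redraws == 0
        np.testing.assert_array_equal(drawn.p_lc_death, params.p_lc_death)
        assert drawn.sensitivity == params.sensitivity

    def test_fixed_seed_reproducible(self, params):
        spec = generate_uncertainty_spec(params, width=0.10)
        a, _ = sample_parameter_set(params, spec, np.random.default_rng(7))
        b, _ = sample_parameter_set(params, spec, np.random.default_rng(7))
        np.testing.assert_array_equal(a.p_cure, b.p_cure)
        assert a.cost_palliative == b.cost_palliative

    def test_sample_means_center_on_base(self, params):
        """CLT check on scalar (non-renormalized) parameters."""
        spec = generate_uncertainty_spec(params, width=0.10)
        ids = ["screening.sensitivity", "onset.scale", "cost.palliative"]
        rng = np.random.default_rng(123)
        draws = {pid: [] for pid in ids}
        for _ in range(2000):
            ps, _ = sample_parameter_set(params, spec, rng)
            for pid in ids:
                draws[pid].append(ps.get_param(pid))
        for pid in ids:
            arr = np.array(draws[pid])
            se = arr.std() / np.sqrt(arr.size)
            assert abs(arr.mean() - params.get_param(pid)) < 3 * se, pid

    def test_drawn_sets_are_valid(self, params):
        spec = generate_uncertainty_spec(params, width=0.10)
        rng = np.random.default_rng(9)
        for _ in range(20):
            ps, _ = sample_parameter_set(params, spec, rng)
            assert ps.validate() == []


class TestNMB:
    def test_published_no_screening_row(self):
        assert nmb(20_000.0, 18_475_224.0, 2520.9) == pytest.approx(31_942_776.0)

    def test_zero_wtp_is_negative_cost(self):
        assert nmb(0.0, 123.0, 4.0) == -123.0

    def test_linear_in_wtp(self):
        rng = np.random.default_rng(2)
        c, q = rng.uniform(0, 1e6), rng.uniform(0, 1e3)
        w = rng.uniform(0, 1e5, size=20)
        lam = rng.uniform()
        for w1, w2 in zip(w[:10], w[10:]):
            mix = lam * w1 + (1 - lam) * w2
            assert nmb(mix, c, q) == pytest.approx(
                lam * nmb(w1, c, q) + (1 - lam) * nmb(w2, c, q), rel=1e-12)


def hand_built_result(rng, n_draws=50, n_scen=3):
    costs = rng.uniform(0, 1e6, size=(n_draws, n_scen))
    qalys = rng.uniform(0, 1e3, size=(n_draws, n_scen))
    return PSAResult([f"s{i}" for i in range(n_scen)], costs, qalys, seed=0)


class TestCEAC:
    def test_single_scenario_probability_one(self):
        res = PSAResult(["only"], np.ones((5, 1)), np.ones((5, 1)), seed=0)
        curves = ceac(res, np.array([0.0, 1e4, 5e4]))
        assert (curves["only"] == 1.0).all()

    def test_zero_wtp_favours_cheapest(self):
        rng = np.random.default_rng(21)
        res = hand_built_result(rng)
        curves = ceac(res, np.array([0.0]))
        cheapest_wins = np.bincount(np.argmin(res.costs, axis=1), minlength=3) / res.n_draws
        np.testing.assert_allclose(curves.iloc[0, 1:].to_numpy(dtype=float), cheapest_wins)

    def test_matches_enumeration_oracle_and_normalizes(self):
        rng = np.random.default_rng(8)
        res = hand_built_result(rng)
        wtp_grid = np.array([0.0, 1e4, 2e4, 1e5])
        curves = ceac(res, wtp_grid)
        for i, w in enumerate(wtp_grid):
            counts = np.zeros(3)
            for d in range(res.n_draws):
                benefits = w * res.qalys[d] - res.costs[d]
                winners = np.flatnonzero(benefits == benefits.max())
                counts[winners] += 1.0 / winners.size
            np.testing.assert_allclose(curves.iloc[i, 1:].to_numpy(dtype=float),
                                       counts / res.n_draws)
        np.testing.assert_allclose(curves.iloc[:, 1:].sum(axis=1), 1.0, atol=1e-9)


class TestCEAF:
    def test_single_scenario_equals_its_ceac(self):
        res = PSAResult(["only"], np.full((4, 1), 3.0), np.full((4, 1), 2.0), seed=0)
        frontier = ceaf(res, np.array([0.0, 1e4]))
        assert (frontier["probability"] == 1.0).all()
        assert (frontier["scenario"] == "only").all()

    def test_never_exceeds_max_ceac(self):
        rng = np.random.default_rng(4)
        res = hand_built_result(rng, n_draws=40, n_scen=4)
        wtp = np.linspace(0, 1e5, 21)
        curves = ceac(res, wtp).iloc[:, 1:]
        frontier = ceaf(res, wtp)
        assert (frontier["probability"] <= curves.max(axis=1).to_numpy() + 1e-12).all()

    def test_degenerate_draws_switch_at_frontier_icers(self):
        """With zero parameter variance the frontier selects by deterministic
        NMB, so switch-points sit at the deterministic sequential ICERs."""
        results = {"a": (100.0, 10.0), "b": (400.0, 20.0), "c": (1300.0, 26.0)}
        # sequential ICERs: a->b 30, b->c 150
        costs = np.tile([v[0] for v in results.values()], (6, 1))
        qalys = np.tile([v[1] for v in results.values()], (6, 1))
        res = PSAResult(list(results), costs, qalys, seed=0)
        wtp = np.arange(0.0, 200.0, 1.0)
        frontier = ceaf(res, wtp)
        # probability 1 everywhere except exact-tie WTPs, where ties split
        assert frontier["probability"].min() >= 0.5
        assert (frontier["probability"] == 1.0).mean() > 0.95
        switches = ceaf_switch_points(frontier)
        assert list(switches["wtp"]) == [31.0, 151.0]  # first grid point past the ICER
        assert list(switches["to_scenario"]) == ["b", "c"]


class TestRunPSA:
    def test_degenerate_single_draw_equals_deterministic(self, params, population, grid):
        scenarios = grid[:3]
        det = evaluate_scenarios(params, scenarios, population)
        res = run_psa(params, UncertaintySpec(), scenarios, population,
                      n_draws=1, seed=0)
        for j, r in enumerate(det.results):
            assert res.costs[0, j] == r.cost
            assert res.qalys[0, j] == r.qalys

    def test_same_seed_identical_draws(self, params, population, grid):
        spec = generate_uncertainty_spec(params, width=0.10)
        scenarios = [grid[0], grid[1]]
        a = run_psa(params, spec, scenarios, population, n_draws=3, seed=11)
        b = run_psa(params, spec, scenarios, population, n_draws=3, seed=11)
        np.testing.assert_array_equal(a.costs, b.costs)
        np.testing.assert_array_equal(a.qalys, b.qalys)

    def test_mean_draws_near_deterministic(self, params, population, grid):
        """Mean-centred distributions keep the Monte Carlo cloud centred on
        the deterministic result (3 SE at modest draw counts)."""
        spec = generate_uncertainty_spec(params, width=0.05)
        scenarios = [grid[0]]
        det = evaluate_scenarios(params, scenarios, population).results[0]
        res = run_psa(params, spec, scenarios, population, n_draws=60, seed=5)
        for got, target in ((res.costs[:, 0], det.cost), (res.qalys[:, 0], det.qalys)):
            se = got.std() / np.sqrt(got.size)
            assert abs(got.mean() - target) < 4 * se
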