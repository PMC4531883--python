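"""PSA sampling, CEAC, tornado DSA and scenario-grid behaviour."""

import numpy as np
import pytest

from visioncea import (
    DistributionSpec,
    ModelParams,
    ceac,
    count_below_threshold,
    default_dsa_ranges,
    default_specs,
    discounted_life_expectancy,
    one_way_dsa,
    run_cohort,
    run_psa,
    sample_params,
    scenario_grid,
)
from visioncea.reference import reported_cells
from visioncea.uncertainty import PsaResult
import pandas as pd


def degenerate_specs(base, lt):
    """All-sd-zero specs: every draw collapses to the base-case means."""
    specs = default_specs(base, lt)
    out = {}
    for name, s in specs.items():
        mean = 51.0 if name == "start_age" else s.mean  # deterministic age is 51
        out[name] = DistributionSpec(name, "fixed", mean, lower=s.lower, upper=s.upper)
    return out


class TestSampleParams:
    def test_zero_sd_reproduces_base_means(self, base_params, synthetic_lt):
        rng = np.random.default_rng(0)
        p = sample_params(degenerate_specs(base_params, synthetic_lt), rng)
        assert p.start_age == 51
        assert p.cost_blind == base_params.cost_blind
        assert p.utility_vimp == base_params.utility_vimp
        assert p.responder_rate == base_params.responder_rate

    def test_same_seed_identical_draws(self, base_params, synthetic_lt):
        specs = default_specs(base_params, synthetic_lt)
        p1 = sample_params(specs, np.random.default_rng(7))
        p2 = sample_params(specs, np.random.default_rng(7))
        assert p1 == p2

    def test_bounds_clamped(self, base_params, synthetic_lt):
        specs = default_specs(base_params, synthetic_lt)
        # absurdly wide utility distribution must still land in [0, 1]
        specs["utility_vimp"] = DistributionSpec(
            "utility_vimp", "normal", 0.77, 50.0, lower=0.0, upper=1.0
        )
        specs["cost_blind"] = DistributionSpec(
            "cost_blind", "normal", 4091.0, 1e7, lower=0.0
        )
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = sample_params(specs, rng)
            assert 0.0 <= p.utility_vimp <= 1.0
            assert p.cost_blind >= 0.0
            assert 18 <= p.start_age <= synthetic_lt.max_age - 1

    def test_missing_spec_rejected(self, base_params, synthetic_lt):
        specs = default_specs(base_params, synthetic_lt)
        del specs["utility_blind"]
        with pytest.raises(KeyError, match="utility_blind"):
            sample_params(specs, np.random.default_rng(0))

    def test_fixed_parameters_never_vary(self, base_params, synthetic_lt):
        specs = default_specs(base_params, synthetic_lt)
        rng = np.random.default_rng(11)
        draws = [sample_params(specs, rng) for _ in range(20)]
        assert {d.responder_rate for d in draws} == {base_params.responder_rate}
        assert {d.discount_costs for d in draws} == {base_params.discount_costs}
        assert {d.discount_effects for d in draws} == {base_params.discount_effects}


class TestRunPsa:
    def test_single_iteration_zero_sd_equals_deterministic(self, base_params, synthetic_lt):
        psa = run_psa(degenerate_specs(base_params, synthetic_lt), synthetic_lt, n_iter=1, seed=0)
        _, avd = run_cohort(base_params, synthetic_lt, "AVD")
        _, bsc = run_cohort(base_params, synthetic_lt, "BSC")
        row = psa.iterations.iloc[0]
        assert row["avd_cost"] == pytest.approx(avd.discounted_cost, abs=1e-9)
        assert row["inc_qaly"] == pytest.approx(
            avd.discounted_qaly - bsc.discounted_qaly, abs=1e-9
        )

    def test_seed_reproducibility_bitwise(self, base_params, synthetic_lt):
        specs = default_specs(base_params, synthetic_lt)
        a = run_psa(specs, synthetic_lt, n_iter=50, seed=42)
        b = run_psa(specs, synthetic_lt, n_iter=50, seed=42)
        pd.testing.assert_frame_equal(a.iterations, b.iterations)

    def test_summary_percentiles_bracket_mean(self, base_params, synthetic_lt):
        psa = run_psa(default_specs(base_params, synthetic_lt), synthetic_lt, n_iter=300, seed=5)
        s = psa.summary
        assert (s["p2.5"] <= s["mean"]).all()
        assert (s["mean"] <= s["p97.5"]).all()

    def test_summary_matches_iterations(self, base_params, synthetic_lt):
        psa = run_psa(default_specs(base_params, synthetic_lt), synthetic_lt, n_iter=200, seed=9)
        assert psa.summary["mean"]["inc_cost"] == pytest.approx(
            psa.iterations["inc_cost"].mean()
        )
        assert psa.summary["sd"]["inc_qaly"] == pytest.approx(
            psa.iterations["inc_qaly"].std(ddof=1)
        )

    def test_mean_converges_to_deterministic_at_large_n(self, base_params, synthetic_lt):
        # the model is linear in every sampled input except starting age, so
        # the PSA mean of incremental QALYs approaches the deterministic
        # value (within 2% at n=10,000)
        psa = run_psa(
            default_specs(base_params, synthetic_lt), synthetic_lt, n_iter=10_000, seed=123
        )
        dle = discounted_life_expectancy(synthetic_lt, 51, 0.03)
        det = base_params.responder_rate * 0.16 * dle
        assert psa.iterations["inc_qaly"].mean() == pytest.approx(det, rel=0.02)


class TestCeac:
    def _psa_from(self, dc, de):
        iters = pd.DataFrame({
            "avd_cost": dc, "bsc_cost": np.zeros_like(dc), "inc_cost": dc,
            "avd_qaly": de, "bsc_qaly": np.zeros_like(de), "inc_qaly": de,
        })
        from visioncea.uncertainty import _summarize
        return PsaResult(iterations=iters, summary=_summarize(iters),
                         n_iter=len(iters), seed=0)

    def test_zero_wtp_counts_cost_saving_iterations(self):
        psa = self._psa_from(np.array([-1.0, 2.0, -3.0, 4.0]), np.ones(4))
        (pt,) = ceac(psa, [0.0])
        assert pt.probability == 0.5

    def test_degenerate_iterations_step_at_break_even(self):
        psa = self._psa_from(np.full(10, 100_000.0), np.full(10, 2.0))
        lo, at, hi = ceac(psa, [49_999.0, 50_000.0, 50_001.0])
        assert lo.probability == 0.0
        assert at.probability == 0.0  # ties are not cost-effective
        assert hi.probability == 1.0

    def test_monotone_when_all_effects_positive(self, base_params, synthetic_lt):
        psa = run_psa(default_specs(base_params, synthetic_lt), synthetic_lt,
                      n_iter=200, seed=21)
        keep = psa.iterations["inc_qaly"] > 0
        sub = psa.iterations[keep].reset_index(drop=True)
        from visioncea.uncertainty import _summarize
        sub_psa = PsaResult(iterations=sub, summary=_summarize(sub),
                            n_iter=len(sub), seed=21)
        probs = [p.probability for p in ceac(sub_psa, np.linspace(0, 2e5, 41))]
        assert np.all(np.diff(probs) >= 0)

    def test_base_case_probability_near_reported(self, base_params, synthetic_lt):
        # reported acceptability at an 80k threshold was 0.63; with the
        # synthetic stand-in life table the probability should be close
        psa = run_psa(default_specs(base_params, synthetic_lt), synthetic_lt,
                      n_iter=1000, seed=1)
        (pt,) = ceac(psa, [80_000.0])
        assert pt.probability == pytest.approx(0.63, abs=0.1)

    def test_empty_grid_rejected(self, base_params, synthetic_lt):
        psa = run_psa(degenerate_specs(base_params, synthetic_lt), synthetic_lt,
                      n_iter=1, seed=0)
        with pytest.raises(ValueError):
            ceac(psa, [])


class TestOneWayDsa:
    def test_degenerate_range_has_zero_spread(self, base_params, synthetic_lt):
        entries = one_way_dsa(base_params, synthetic_lt,
                              {"cost_blind": (4091.0, 4091.0)})
        assert entries[0].spread == pytest.approx(0.0)

    def test_non_bracketing_range_rejected(self, base_params, synthetic_lt):
        with pytest.raises(ValueError, match="bracket"):
            one_way_dsa(base_params, synthetic_lt, {"responder_rate": (0.7, 0.9)})

    def test_responder_rate_has_largest_spread(self, base_params, synthetic_lt):
        entries = one_way_dsa(base_params, synthetic_lt)
        assert entries[0].parameter == "responder_rate"
        assert entries[0].spread > max(e.spread for e in entries[1:])

    def test_effect_discounting_direction(self, base_params, synthetic_lt):
        # effects accrue over a lifetime while costs are front-loaded, so a
        # higher effect discount rate worsens (raises) the ICER
        (entry,) = one_way_dsa(base_params, synthetic_lt,
                               {"discount_effects": (0.0, 0.05)})
        assert entry.icer_low < entry.icer_high

    def test_sorted_by_spread_descending(self, base_params, synthetic_lt):
        entries = one_way_dsa(base_params, synthetic_lt)
        spreads = [e.spread for e in entries]
        assert spreads == sorted(spreads, reverse=True)


class TestScenarioGrid:
    def test_default_grid_has_25_cells(self, base_params, synthetic_lt):
        cells = scenario_grid(params=base_params, lt=synthetic_lt)
        assert len(cells) == 25

    def test_effect_constant_within_cost_column(self, base_params, synthetic_lt):
        # device cost cannot influence QALYs
        cells = scenario_grid(params=base_params, lt=synthetic_lt)
        by_rr = {}
        for c in cells:
            by_rr.setdefault(c.responder_rate, set()).add(round(c.delta_effect, 12))
        assert all(len(v) == 1 for v in by_rr.values())

    def test_icer_ordering_across_rows_and_columns(self, base_params, synthetic_lt):
        cells = scenario_grid(params=base_params, lt=synthetic_lt)
        # increasing in first-year cost at fixed RR
        for rr in {c.responder_rate for c in cells}:
            row = sorted((c for c in cells if c.responder_rate == rr),
                         key=lambda c: c.first_year_cost)
            icers = [c.icer for c in row]
            assert all(a < b for a, b in zip(icers, icers[1:]))
        # decreasing in RR at fixed cost
        for cost in {c.first_year_cost for c in cells}:
            col = sorted((c for c in cells if c.first_year_cost == cost),
                         key=lambda c: c.responder_rate)
            icers = [c.icer for c in col]
            assert all(a > b for a, b in zip(icers, icers[1:]))

    def test_psa_mode_close_to_deterministic(self, base_params, synthetic_lt):
        det = scenario_grid([0.625], [85_000.0], base_params, synthetic_lt)
        psa = scenario_grid([0.625], [85_000.0], base_params, synthetic_lt,
                            mode="psa", n_iter=400, seed=2)
        assert psa[0].delta_effect == pytest.approx(det[0].delta_effect, rel=0.15)
        assert psa[0].delta_cost == pytest.approx(det[0].delta_cost, rel=0.15)

    def test_empty_lists_rejected(self, base_params, synthetic_lt):
        with pytest.raises(ValueError):
            scenario_grid([], [85_000.0], base_params, synthetic_lt)


class TestCountBelowThreshold:
    @pytest.mark.parametrize("wtp,expected", [(40_000, 7), (60_000, 15), (80_000, 19)])
    def test_reported_grid_counts(self, wtp, expected):
        assert count_below_threshold(reported_cells(), wtp) == expected

    def test_zero_threshold_counts_nothing(self):
        assert count_below_threshold(reported_cells(), 0.0) == 0


class TestDefaultDsaRanges:
    def test_all_ranges_bracket_base(self, base_params):
        ranges = default_dsa_ranges(base_params)
        for name, (lo, hi) in ranges.items():
            base = getattr(base_params, name)
            if "lifetime" in (lo, hi) or base == "lifetime":
                continue
            assert lo <= base <= hi
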