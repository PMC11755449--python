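"""Stage-gated development costs, sales cash flows and rNPV."""

import math

import numpy as np
import pytest

from smartavg import (
    DevelopmentStage,
    breakeven_effectiveness,
    dev_cost_pv,
    forecast_units,
    reach_probabilities,
    rnpv,
    run_cua,
    sales_cashflows,
)

DISC = 0.104


class TestReachProbabilities:
    def test_rounded_schedule_cumulates_close_to_base(self, bundle):
        # the same schedule with its probabilities rounded to 3 decimals
        stages = [s.model_copy(update={"p_success": p}) for s, p in
                  zip(bundle.stages, (0.778, 0.778, 0.778, 0.48, 0.757,
                                      0.805))]
        reach, cum = reach_probabilities(stages)
        assert reach[0] == 1.0
        assert math.isclose(reach[3], 0.778 ** 3, rel_tol=1e-12)
        assert math.isclose(cum, 0.778 ** 3 * 0.48 * 0.757 * 0.805,
                            rel_tol=1e-12)

    def test_base_case_cumulates_to_13_75_percent(self, bundle):
        _, cum = reach_probabilities(bundle.stages)
        assert round(cum * 100, 2) == 13.75
        assert round(cum * 100, 1) == 13.7

    def test_single_certain_stage(self):
        stage = DevelopmentStage(name="only", cost=1.0, p_success=1.0,
                                 duration_years=1, start_elapsed_years=0)
        reach, cum = reach_probabilities([stage])
        assert list(reach) == [1.0] and cum == 1.0

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            reach_probabilities([])


class TestDevCostPv:
    def test_base_case_present_value(self, bundle):
        pv = dev_cost_pv(bundle.stages, DISC)
        assert math.isclose(pv, 33_282_266, rel_tol=0.005)

    def test_no_discount_no_risk_is_plain_sum(self, bundle):
        stages = [s.model_copy(update={"p_success": 1.0})
                  for s in bundle.stages]
        assert math.isclose(dev_cost_pv(stages, 0.0), 115_411_235.0,
                            rel_tol=1e-12)

    def test_single_stage_at_time_zero_ignores_discount(self):
        stage = DevelopmentStage(name="s", cost=123.0, p_success=0.5,
                                 duration_years=1, start_elapsed_years=0)
        for disc in (0.0, 0.104, 0.5):
            assert dev_cost_pv([stage], disc) == 123.0

    def test_stage_splitting_invariance(self, bundle):
        """Splitting a stage into consecutive sub-stages whose probabilities
        multiply to the original, with the full cost carried by the first
        sub-stage at the same start time, leaves the PV unchanged -- the
        equivalence behind the eight-stage two-way reparameterization."""
        stages = list(bundle.stages)
        s = stages[3]
        q = s.p_success ** (1 / 3)
        parts = [s.model_copy(update={"cost": s.cost if k == 0 else 0.0,
                                      "p_success": q}) for k in range(3)]
        split = stages[:3] + parts + stages[4:]
        assert math.isclose(dev_cost_pv(split, DISC),
                            dev_cost_pv(bundle.stages, DISC), rel_tol=1e-12)
        _, cum_split = reach_probabilities(split)
        _, cum_base = reach_probabilities(bundle.stages)
        assert math.isclose(cum_split, cum_base, rel_tol=1e-12)


class TestForecast:
    def test_total_units(self, bundle):
        units, total = forecast_units(bundle.market)
        assert math.isclose(total, 130_368.0, abs_tol=1e-6)

    def test_2036_units(self, bundle):
        units, _ = forecast_units(bundle.market)
        assert math.isclose(units.loc[2036], 21_300 * 0.30, rel_tol=1e-12)

    def test_total_is_unrounded_sum(self, bundle):
        # the per-year display values sum to 130,367; the model carries units
        # unrounded, whose sum rounds to 130,368
        displayed = [3179, 6390, 9631, 12902, 16201, 16274, 16344, 16414,
                     16482, 16550]
        assert sum(displayed) == 130_367
        _, total = forecast_units(bundle.market)
        assert round(total) == 130_368

    def test_zero_penetration(self, bundle):
        market = bundle.market.model_copy(deep=True)
        for y in market.years:
            y.penetration = 0.0
        assert forecast_units(market)[1] == 0.0


class TestSalesCashflows:
    def test_zero_margin_price(self, bundle):
        price = 100.0 / 0.7
        flows = sales_cashflows(price, bundle.market, bundle.commercial)
        np.testing.assert_allclose(flows["net_cash"], 0.0, atol=1e-9)

    def test_zero_price_charges_cogs_only(self, bundle):
        flows = sales_cashflows(0.0, bundle.market, bundle.commercial)
        units, _ = forecast_units(bundle.market)
        np.testing.assert_allclose(flows["sga"], 0.0)
        np.testing.assert_allclose(flows["net_cash"], -100.0 * units)

    def test_margin_at_reference_price(self, bundle):
        flows = sales_cashflows(22_455.31, bundle.market, bundle.commercial)
        per_unit = flows["net_cash"] / flows["units"]
        np.testing.assert_allclose(per_unit, 0.7 * 22_455.31 - 100.0,
                                   rtol=1e-12)

    def test_negative_price_rejected(self, bundle):
        with pytest.raises(ValueError):
            sales_cashflows(-1.0, bundle.market, bundle.commercial)


class TestRnpv:
    def test_zero_margin_price_gives_minus_dev_cost(self, bundle):
        res = rnpv(100.0 / 0.7, bundle.stages, bundle.market,
                   bundle.commercial)
        assert math.isclose(res.rnpv, -res.dev_cost_pv, rel_tol=1e-12)

    def test_decomposition_identity(self, bundle):
        res = rnpv(20_000.0, bundle.stages, bundle.market, bundle.commercial)
        assert math.isclose(res.rnpv, res.sales_pv - res.dev_cost_pv,
                            rel_tol=1e-12)
        # the year-by-year schedule reproduces the same total
        assert math.isclose(res.schedule["rnc_pv"].sum(), res.rnpv,
                            rel_tol=1e-9)

    def test_monotone_in_price(self, bundle):
        vals = [rnpv(p, bundle.stages, bundle.market, bundle.commercial).rnpv
                for p in (0.0, 5_000, 15_000, 30_000)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_certain_undiscounted_is_plain_sum(self, bundle):
        stages = [s.model_copy(update={"p_success": 1.0})
                  for s in bundle.stages]
        commercial = bundle.commercial.model_copy(
            update={"ococ_discount_rate": 1e-12})
        price = 10_000.0
        res = rnpv(price, stages, bundle.market, commercial)
        units, total = forecast_units(bundle.market)
        expected = total * (0.7 * price - 100.0) - sum(s.cost for s in stages)
        assert math.isclose(res.rnpv, expected, rel_tol=1e-6)

    def test_monetary_outputs_scale_linearly(self, bundle):
        k = 3.5
        stages = [s.model_copy(update={"cost": k * s.cost})
                  for s in bundle.stages]
        commercial = bundle.commercial.model_copy(
            update={"cogs_per_unit": k * bundle.commercial.cogs_per_unit})
        res1 = rnpv(10_000.0, bundle.stages, bundle.market, bundle.commercial)
        resk = rnpv(k * 10_000.0, stages, bundle.market, commercial)
        assert math.isclose(resk.rnpv, k * res1.rnpv, rel_tol=1e-12)


class TestBreakeven:
    def test_zero_dev_cost_breaks_even_at_margin_price(self, bundle):
        stages = [s.model_copy(update={"cost": 0.0}) for s in bundle.stages]
        b = bundle.model_copy(update={"stages": stages})
        pct, price = breakeven_effectiveness(b)
        threshold = 100.0 / 0.7
        assert price > threshold
        assert run_cua(b, (pct - 1) / 100.0).inmb <= threshold

    def test_zero_market_never_breaks_even(self, bundle):
        market = bundle.market.model_copy(deep=True)
        for y in market.years:
            y.market_size = 0.0
        b = bundle.model_copy(update={"market": market})
        assert breakeven_effectiveness(b) is None
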