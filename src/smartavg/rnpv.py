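"""Risk-adjusted net present value of the full development-to-market lifecycle.

Cash flows are yearly, with the base year (2023) as t = 0:

* Stage costs are lumps at each stage's elapsed start year, weighted by the
  probability of *reaching* the stage (the product of all preceding stages'
  success probabilities; the first stage is reached with certainty).
* Sales run over the market-forecast years.  Net cash in year y is
  units_y * ((1 - sga) * price - cogs); every sales flow is weighted by the
  final cumulative probability of development success.
* Everything is discounted at the opportunity cost of capital:
  rNPV = sum_t rNC_t / (1 + disc)^t.

The unit price is the CUA headroom price INMB(e), linking commercial value to
the assumed device effectiveness.  A positive rNPV means the expected return
exceeds the cost of capital.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .markov import run_cua
from .parameters import (
    CommercialSettings,
    DevelopmentStage,
    MarketForecast,
    ParameterBundle,
    require_valid,
)


def reach_probabilities(
    stages: Sequence[DevelopmentStage],
) -> tuple[np.ndarray, float]:
    """Per-stage reach probabilities and the final cumulative probability.

    Stage k is reached with the product of the success probabilities of
    stages 1..k-1 (the first stage with probability 1); the cumulative
    probability of getting to market is the product over all stages.
    """
    if not stages:
        raise ValueError("stage schedule is empty")
    ps = np.array([s.p_success for s in stages], dtype=float)
    reach = np.concatenate([[1.0], np.cumprod(ps[:-1])])
    return reach, float(np.prod(ps))


def dev_cost_pv(stages: Sequence[DevelopmentStage], disc: float,
                weights: np.ndarray | None = None) -> float:
    """Probability-weighted present value of the development schedule.

    Each stage's cost is a lump at its elapsed start year.  ``weights``
    overrides the reach probabilities (used by the two-way sensitivity
    reparameterization).
    """
    if disc <= -1:
        raise ValueError("discount rate must exceed -1")
    if weights is None:
        weights, _ = reach_probabilities(stages)
    costs = np.array([s.cost for s in stages], dtype=float)
    starts = np.array([s.start_elapsed_years for s in stages], dtype=float)
    return float(np.sum(costs * np.asarray(weights)
                        / (1.0 + disc) ** starts))


def forecast_units(market: MarketForecast) -> tuple[pd.Series, float]:
    """Per-year forecast units (size x penetration, unrounded) and their total."""
    units = pd.Series(market.units, index=market.calendar_years, name="units")
    return units, float(units.sum())


def sales_cashflows(price: float, market: MarketForecast,
                    commercial: CommercialSettings) -> pd.DataFrame:
    """Per-year sales cash flows before risk weighting.

    Revenue = units * price; SG&A is charged on realized revenue only, COGS
    per unit sold, so net cash = units * ((1 - sga) * price - cogs).
    """
    if price < 0:
        raise ValueError("price must be >= 0")
    units, _ = forecast_units(market)
    dev_free_year = commercial.base_year
    if (units.index < dev_free_year).any():
        raise ValueError("sales years precede the base year")
    revenue = units * price
    sga = commercial.sga_fraction_of_revenue * revenue
    cogs = commercial.cogs_per_unit * units
    net = revenue - sga - cogs
    return pd.DataFrame(
        {"units": units, "revenue": revenue, "cogs": cogs, "sga": sga,
         "net_cash": net}
    )


@dataclass(frozen=True)
class RnpvResult:
    """rNPV decomposition: development cost PV, sales PV, and the schedule."""

    price: float
    dev_cost_pv: float
    sales_pv: float
    rnpv: float
    cumulative_probability: float
    schedule: pd.DataFrame


def rnpv(price: float, stages: Sequence[DevelopmentStage],
         market: MarketForecast, commercial: CommercialSettings,
         stage_weights: np.ndarray | None = None,
         sales_weight: float | None = None) -> RnpvResult:
    """Risk-adjusted NPV at a given unit price.

    ``stage_weights`` / ``sales_weight`` override the reach probabilities and
    the final cumulative probability (two-way sensitivity); by default both
    derive from the stage schedule.
    """
    reach, cum = reach_probabilities(stages)
    if stage_weights is None:
        stage_weights = reach
    if sales_weight is None:
        sales_weight = cum
    disc = commercial.ococ_discount_rate

    cost_pv = dev_cost_pv(stages, disc, weights=stage_weights)

    sales = sales_cashflows(price, market, commercial)
    t_sales = sales.index.to_numpy() - commercial.base_year
    df_sales = (1.0 + disc) ** (-t_sales.astype(float))
    weighted_net = sales_weight * sales["net_cash"].to_numpy()
    sales_pv = float(np.sum(weighted_net * df_sales))

    # year-by-year risk-adjusted schedule (dev outflows + weighted sales)
    years: dict[int, dict] = {}
    for s, w in zip(stages, np.asarray(stage_weights)):
        y = commercial.base_year + int(round(s.start_elapsed_years))
        row = years.setdefault(y, {"dev_cost": 0.0, "net_sales": 0.0})
        row["dev_cost"] += w * s.cost
    for y, net, w in zip(sales.index, sales["net_cash"], [sales_weight] * len(sales)):
        row = years.setdefault(int(y), {"dev_cost": 0.0, "net_sales": 0.0})
        row["net_sales"] += w * net
    sched = pd.DataFrame.from_dict(years, orient="index").sort_index()
    sched.index.name = "year"
    sched["rnc"] = sched["net_sales"] - sched["dev_cost"]
    t = sched.index.to_numpy() - commercial.base_year
    sched["discount_factor"] = (1.0 + disc) ** (-t.astype(float))
    sched["rnc_pv"] = sched["rnc"] * sched["discount_factor"]

    return RnpvResult(
        price=price,
        dev_cost_pv=cost_pv,
        sales_pv=sales_pv,
        rnpv=sales_pv - cost_pv,
        cumulative_probability=float(sales_weight),
        schedule=sched,
    )


def rnpv_at_effectiveness(bundle: ParameterBundle, e: float,
                          **kwargs) -> RnpvResult:
    """rNPV priced at the CUA headroom price INMB(e)."""
    require_valid(bundle)
    price = max(run_cua(bundle, e).inmb, 0.0)
    return rnpv(price, bundle.stages, bundle.market, bundle.commercial,
                **kwargs)


def breakeven_effectiveness(
    bundle: ParameterBundle,
) -> tuple[int, float] | None:
    """Smallest integer-percent effectiveness with a positive base-case rNPV.

    Scans e = 1%..100%, pricing each run at its headroom price INMB(e).
    Returns ``(percent, price)`` or ``None`` if the rNPV never turns positive.
    """
    require_valid(bundle)
    for pct in range(1, 101):
        price = run_cua(bundle, pct / 100.0).inmb
        if price < 0:
            continue
        result = rnpv(price, bundle.stages, bundle.market, bundle.commercial)
        if result.rnpv > 0:
            return pct, price
    return None
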