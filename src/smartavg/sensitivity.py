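"""Two-way sensitivity of rNPV over effectiveness x cumulative success.

To vary the cumulative probability of development success X as a single
scenario axis, the schedule is reparameterized to eight equal-probability
stages: the clinical safety study (whose base-case success probability is
well below the others') is split into three sub-stages in probability space,
so that

    X = y**8,    y = X**(1/8)

with y the common per-stage probability.  The six *cost* stages keep their
original costs and start times; only their reach weights change, to
(1, y, y^2, y^3, y^6, y^7) -- the safety-study cost is weighted by y^3
(the probability of reaching its first sub-stage) and the pivotal trial by
y^6 (after all three sub-stages).  Sales flows carry the full cumulative
probability X = y^8.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .markov import run_cua
from .parameters import ParameterBundle, require_valid
from .rnpv import rnpv

#: reach-weight exponents of the six cost stages under the 8-stage scheme
STAGE_WEIGHT_EXPONENTS = (0, 1, 2, 3, 6, 7)


@dataclass(frozen=True)
class TwoWayParams:
    """Reparameterized weights at one cumulative probability X."""

    x: float
    y: float
    stage_weights: tuple[float, ...]
    sales_weight: float


def reparameterize(x: float) -> TwoWayParams:
    """Eight-stage equal-probability weights for cumulative probability ``x``."""
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"cumulative probability must be in [0, 1], got {x}")
    y = x ** (1.0 / 8.0)
    weights = tuple(y ** k for k in STAGE_WEIGHT_EXPONENTS)
    return TwoWayParams(x=x, y=y, stage_weights=weights, sales_weight=y ** 8)


@dataclass(frozen=True)
class TwoWayGrid:
    """rNPV (USD) per (cumulative probability, effectiveness) cell."""

    x_values: tuple[float, ...]
    e_values: tuple[float, ...]
    prices: tuple[float, ...]
    cells: pd.DataFrame  # index = X, columns = e

    def cell(self, x: float, e: float) -> float:
        return float(self.cells.loc[x, e])


def two_way_grid(bundle: ParameterBundle, x_values: Sequence[float],
                 e_values: Sequence[float]) -> TwoWayGrid:
    """rNPV grid over cumulative success probability x effectiveness.

    Headroom prices are computed once per effectiveness level and reused
    across rows; the schedule requires exactly six cost stages (the scheme's
    weight exponents are tied to that layout).
    """
    require_valid(bundle)
    if len(bundle.stages) != len(STAGE_WEIGHT_EXPONENTS):
        raise ValueError(
            "two-way reparameterization expects a "
            f"{len(STAGE_WEIGHT_EXPONENTS)}-stage schedule"
        )
    x_values = tuple(float(x) for x in x_values)
    e_values = tuple(float(e) for e in e_values)
    prices = tuple(max(run_cua(bundle, e).inmb, 0.0) for e in e_values)

    data = np.empty((len(x_values), len(e_values)))
    for i, x in enumerate(x_values):
        params = reparameterize(x)
        for j, price in enumerate(prices):
            res = rnpv(price, bundle.stages, bundle.market, bundle.commercial,
                       stage_weights=np.array(params.stage_weights),
                       sales_weight=params.sales_weight)
            data[i, j] = res.rnpv
    cells = pd.DataFrame(data, index=list(x_values), columns=list(e_values))
    cells.index.name = "cumulative_probability"
    cells.columns.name = "effectiveness"
    return TwoWayGrid(x_values=x_values, e_values=e_values, prices=prices,
                      cells=cells)
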