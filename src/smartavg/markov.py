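"""Markov cohort cost-utility engine and INMB headroom pricing.

The four-state monthly model (functional graft, failed graft, CVC, dead) is
run for both arms over a 60-cycle (5-year) horizon.  The comparator arm uses
the base transition probabilities; the smart-graft arm scales the monthly
functional->failed probability by (1 - e), where e is the assumed device
effectiveness, returning the released mass to continued function (the device
prevents failure, not death).

The headroom price at willingness-to-pay threshold lambda is the incremental
net monetary benefit

    INMB(e) = lambda * dQALY(e) - dCost(e),

the largest price premium at which the smart graft stays cost-effective.

Accrual and discounting conventions are set on
:class:`~smartavg.parameters.EconSettings`; see its docstring.  With monthly
cycles, a month in a state earns utility/12 QALYs, 1/12 life-years if alive,
and the state's monthly cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decision_tree import InitialDistribution, tree_outcomes
from .parameters import (
    STATES,
    EconSettings,
    MarkovParameters,
    ParameterBundle,
    require_valid,
)

F, X, C, D = 0, 1, 2, 3  # state indices: functional, failed (X), cvc, dead


def transition_matrix(markov: MarkovParameters) -> np.ndarray:
    """4x4 row-stochastic monthly transition matrix in STATES order."""
    return np.array(
        [
            [markov.p_functional_to_functional, markov.p_functional_to_failed,
             0.0, markov.p_functional_to_dead],
            [markov.p_failed_to_functional, markov.p_failed_to_failed,
             markov.p_failed_to_cvc, markov.p_failed_to_dead],
            [0.0, 0.0, markov.p_cvc_to_cvc, markov.p_cvc_to_dead],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def apply_effectiveness(markov: MarkovParameters, e: float) -> MarkovParameters:
    """Scale the functional->failed probability by (1 - e).

    The removed probability mass is added to continued function; the
    functional->dead probability and every other row are unchanged, so each
    row still sums to 1.
    """
    if not 0.0 <= e <= 1.0:
        raise ValueError(f"effectiveness must be in [0, 1], got {e}")
    p_fail = markov.p_functional_to_failed * (1.0 - e)
    released = markov.p_functional_to_failed - p_fail
    return markov.model_copy(
        update={
            "p_functional_to_failed": p_fail,
            "p_functional_to_functional":
                markov.p_functional_to_functional + released,
        }
    )


def _accrual_weights(econ: EconSettings) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle (occupancy mix weight, discount factor) for cycles 1..N.

    Returns the month indices at which each cycle's accrual is valued and the
    corresponding discount factors.
    """
    n = econ.horizon_cycles
    t = np.arange(1, n + 1, dtype=float)
    if econ.accrual == "start":
        m = t - 1.0
    elif econ.accrual == "end":
        m = t
    else:  # half-cycle correction
        m = t - 0.5
    r = econ.annual_discount_rate
    months = m * econ.cycle_length_months
    if econ.discounting == "monthly":
        df = (1.0 + r) ** (-(months / 12.0))
    else:
        df = (1.0 + r) ** (-np.floor(months / 12.0))
    return m, df


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancies and discounted accruals of one arm.

    ``occupancy`` has shape (N+1, 4) in STATES order; row 0 is the tree-exit
    distribution.  The accrual arrays have length N (cycles 1..N).
    """

    occupancy: np.ndarray
    disc_cost: np.ndarray
    disc_qaly: np.ndarray
    disc_ly: np.ndarray

    @property
    def total_cost(self) -> float:
        return float(self.disc_cost.sum())

    @property
    def total_qalys(self) -> float:
        return float(self.disc_qaly.sum())

    @property
    def total_lys(self) -> float:
        return float(self.disc_ly.sum())

    @property
    def survival(self) -> float:
        """Alive fraction at the end of the horizon."""
        return float(1.0 - self.occupancy[-1, D])

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "cycle", np.arange(len(df)))
        for name, arr in (("disc_cost", self.disc_cost),
                          ("disc_qaly", self.disc_qaly),
                          ("disc_ly", self.disc_ly)):
            df[name] = np.concatenate([[0.0], arr])
        return df


def initial_occupancy(initial: InitialDistribution,
                      econ: EconSettings) -> np.ndarray:
    """Tree-exit distribution as a state-occupancy vector.

    When ``tree_cvc_enters_markov`` is off, tree-CVC patients are treated as
    leaving the model (parked in the absorbing state) instead of accruing
    CVC costs; incremental results are identical either way because the tree
    is shared.
    """
    occ = np.zeros(4)
    occ[F] = initial.share_functional
    if econ.tree_cvc_enters_markov:
        occ[C] = initial.share_cvc
        occ[D] = initial.share_dead
    else:
        occ[D] = initial.share_dead + initial.share_cvc
    return occ


def cohort_trace(initial: InitialDistribution, markov: MarkovParameters,
                 econ: EconSettings) -> CohortTrace:
    """Run the cohort recursion and accumulate discounted accruals."""
    n = econ.horizon_cycles
    P = transition_matrix(markov)
    occ = np.empty((n + 1, 4))
    occ[0] = initial_occupancy(initial, econ)
    for t in range(n):
        occ[t + 1] = occ[t] @ P

    m, df = _accrual_weights(econ)
    if econ.accrual == "start":
        mix = occ[:-1]
    elif econ.accrual == "end":
        mix = occ[1:]
    else:
        mix = 0.5 * (occ[:-1] + occ[1:])

    frac = econ.cycle_length_months / 12.0
    cost_rates = np.array([0.0, markov.cost_failed_monthly,
                           markov.cost_cvc_monthly, 0.0])
    cost_rates = cost_rates * econ.cycle_length_months
    qaly_rates = np.array([markov.utility_functional, markov.utility_failed,
                           markov.utility_cvc, 0.0]) * frac
    ly_rates = np.array([1.0, 1.0, 1.0, 0.0]) * frac

    return CohortTrace(
        occupancy=occ,
        disc_cost=df * (mix @ cost_rates),
        disc_qaly=df * (mix @ qaly_rates),
        disc_ly=df * (mix @ ly_rates),
    )


@dataclass(frozen=True)
class CuaResult:
    """Discounted per-arm totals, incrementals and INMB at one effectiveness."""

    effectiveness: float
    p_fail_smart: float
    cost_eptfe: float
    cost_smart: float
    qalys_eptfe: float
    qalys_smart: float
    lys_eptfe: float
    lys_smart: float
    incremental_cost: float
    incremental_qalys: float
    incremental_lys: float
    inmb: float
    trace_eptfe: CohortTrace | None = None
    trace_smart: CohortTrace | None = None

    def row(self) -> dict:
        return {
            "effectiveness": self.effectiveness,
            "p_functional_to_failed_smart": self.p_fail_smart,
            "incremental_cost": self.incremental_cost,
            "incremental_qalys": self.incremental_qalys,
            "incremental_lys": self.incremental_lys,
            "inmb": self.inmb,
        }


def run_cua(bundle: ParameterBundle, e: float,
            keep_traces: bool = False) -> CuaResult:
    """Cost-utility comparison of the smart graft (at effectiveness e) vs ePTFE.

    Both arms start from the shared decision-tree distribution and carry the
    same one-time expected tree cost; the smart arm's functional->failed
    probability is scaled by (1 - e).
    """
    require_valid(bundle)
    initial = tree_outcomes(bundle.tree)
    smart = apply_effectiveness(bundle.markov, e)
    tr0 = cohort_trace(initial, bundle.markov, bundle.econ)
    tr1 = cohort_trace(initial, smart, bundle.econ)
    cost0 = initial.expected_initial_cost + tr0.total_cost
    cost1 = initial.expected_initial_cost + tr1.total_cost
    d_cost = cost1 - cost0
    d_qaly = tr1.total_qalys - tr0.total_qalys
    return CuaResult(
        effectiveness=e,
        p_fail_smart=smart.p_functional_to_failed,
        cost_eptfe=cost0,
        cost_smart=cost1,
        qalys_eptfe=tr0.total_qalys,
        qalys_smart=tr1.total_qalys,
        lys_eptfe=tr0.total_lys,
        lys_smart=tr1.total_lys,
        incremental_cost=d_cost,
        incremental_qalys=d_qaly,
        incremental_lys=tr1.total_lys - tr0.total_lys,
        inmb=bundle.econ.wtp_lambda * d_qaly - d_cost,
        trace_eptfe=tr0 if keep_traces else None,
        trace_smart=tr1 if keep_traces else None,
    )


def effectiveness_sweep(bundle: ParameterBundle,
                        grid: "list[float] | np.ndarray") -> list[CuaResult]:
    """One :class:`CuaResult` per effectiveness level."""
    grid = list(grid)
    if any(not 0.0 <= e <= 1.0 for e in grid):
        raise ValueError("effectiveness grid values must lie in [0, 1]")
    return [run_cua(bundle, float(e)) for e in grid]


def sweep_frame(results: list[CuaResult]) -> pd.DataFrame:
    """Sweep results in the standard table layout (one row per level)."""
    return pd.DataFrame([r.row() for r in results])


def failure_burden(bundle: ParameterBundle) -> tuple[float, float, float]:
    """Discounted loss attributable to graft failure after successful implant.

    Defined as the difference between the base (ePTFE) arm and a zero-failure
    counterfactual: the same model with the functional->failed probability set
    to 0 (effectiveness 1), everything else unchanged.  Returns positive
    losses (life-years, QALYs, USD).  Equivalently the negated incrementals
    of :func:`run_cua` at e = 1.
    """
    res = run_cua(bundle, 1.0)
    return (res.incremental_lys, res.incremental_qalys, -res.incremental_cost)
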