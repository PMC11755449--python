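"""Patient-level microsimulation oracle and random scenario generator.

The microsimulation pushes individual patients through the placement tree
(one categorical draw over the six terminal paths) and 60 monthly Markov
transitions, accruing discounted costs, QALYs and life-years under exactly
the same convention flags as the cohort engine.  Its sample means must agree
with the cohort totals within Monte-Carlo error, which validates the cohort
recursion against brute force.

The scenario generator draws full parameter bundles with the same structure
as the base case for property-based testing: simplex transition rows with
monthly death rates ordered failed, CVC >= functional; utilities in
[0.3, 0.9] with functional >= failed and functional >= CVC; log-uniform
costs; stage probabilities in [0.3, 0.95]; monotone capped penetration
schedules.  The orderings encode the clinical structure (a failed graft or a
catheter never beats a functioning graft on survival or quality of life);
without them, reducing graft failure need not be beneficial and the model's
monotonicity properties would not be expected to hold.  A fixed share of
draws hits degenerate corners (zero failure probability, zero market).

Randomness protocol: one root seed; patient i consumes row i of a
pre-generated uniform array, so results do not depend on any iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decision_tree import tree_outcomes
from .markov import C, D, F, X, apply_effectiveness, transition_matrix, _accrual_weights
from .parameters import (
    CommercialSettings,
    DevelopmentStage,
    EconSettings,
    MarketForecast,
    MarketYear,
    MarkovParameters,
    ParameterBundle,
    TreeParameters,
    require_valid,
)

# terminal tree paths in draw order
_TREE_PATHS = (
    "death_procedure", "death_maturation", "mature_functional",
    "death_nonmaturation", "cvc_nonmaturation", "functional_after_intervention",
)


@dataclass(frozen=True)
class MicrosimResult:
    """Monte-Carlo summary of one microsimulation run."""

    n_patients: int
    seed: int
    effectiveness: float
    mean_cost: float
    se_cost: float
    mean_qalys: float
    se_qalys: float
    mean_lys: float
    se_lys: float
    survival: float

    def row(self) -> dict:
        return self.__dict__.copy()


def _tree_draw(tree: TreeParameters, u: np.ndarray,
               econ: EconSettings) -> tuple[np.ndarray, np.ndarray]:
    """Initial Markov state and one-time cost per patient from one uniform."""
    probs = np.array(tree.path_probabilities, dtype=float)
    probs = probs / probs.sum()
    edges = np.cumsum(probs)
    path = np.searchsorted(edges, u, side="right")
    path = np.minimum(path, len(probs) - 1)

    state = np.empty(u.shape, dtype=np.int64)
    state[(path == 0) | (path == 1) | (path == 3)] = D
    state[(path == 2) | (path == 5)] = F
    state[path == 4] = C if econ.tree_cvc_enters_markov else D

    cost = np.full(u.shape, tree.cost_placement)
    nonmat = (path == 3) | (path == 4) | (path == 5)
    cost[nonmat] += tree.cost_revision
    cost[path == 4] += tree.cost_cvc_placement
    return state, cost


def microsimulate(bundle: ParameterBundle, e: float, n: int,
                  seed: int) -> MicrosimResult:
    """Simulate ``n`` patients through tree + Markov at effectiveness ``e``.

    Fully reproducible given ``seed``; accrual and discounting follow
    ``bundle.econ`` exactly as in :func:`smartavg.markov.cohort_trace`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    require_valid(bundle)
    econ = bundle.econ
    markov = apply_effectiveness(bundle.markov, e)
    ncyc = econ.horizon_cycles

    rng = np.random.default_rng(seed)
    # row i is patient i's stream: column 0 the tree draw, then one per cycle
    U = rng.random((n, ncyc + 1))

    state, cost = _tree_draw(bundle.tree, U[:, 0], econ)
    qaly = np.zeros(n)
    ly = np.zeros(n)

    P = transition_matrix(markov)
    cumP = np.cumsum(P, axis=1)
    frac = econ.cycle_length_months / 12.0
    cost_rates = np.array([0.0, markov.cost_failed_monthly,
                           markov.cost_cvc_monthly, 0.0]) * econ.cycle_length_months
    qaly_rates = np.array([markov.utility_functional, markov.utility_failed,
                           markov.utility_cvc, 0.0]) * frac
    ly_rates = np.array([1.0, 1.0, 1.0, 0.0]) * frac
    _, df = _accrual_weights(econ)

    for t in range(1, ncyc + 1):
        prev = state
        state = (U[:, t, None] >= cumP[prev]).sum(axis=1)
        if econ.accrual == "start":
            cmix, qmix, lmix = cost_rates[prev], qaly_rates[prev], ly_rates[prev]
        elif econ.accrual == "end":
            cmix, qmix, lmix = cost_rates[state], qaly_rates[state], ly_rates[state]
        else:
            cmix = 0.5 * (cost_rates[prev] + cost_rates[state])
            qmix = 0.5 * (qaly_rates[prev] + qaly_rates[state])
            lmix = 0.5 * (ly_rates[prev] + ly_rates[state])
        d = df[t - 1]
        cost += d * cmix
        qaly += d * qmix
        ly += d * lmix

    def se(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    return MicrosimResult(
        n_patients=n, seed=seed, effectiveness=e,
        mean_cost=float(cost.mean()), se_cost=se(cost),
        mean_qalys=float(qaly.mean()), se_qalys=se(qaly),
        mean_lys=float(ly.mean()), se_lys=se(ly),
        survival=float((state != D).mean()),
    )


def cohort_expectations(bundle: ParameterBundle,
                        e: float) -> tuple[float, float, float, float]:
    """Cohort-engine (cost, QALY, LY, survival) per patient, for comparison."""
    from .markov import cohort_trace

    initial = tree_outcomes(bundle.tree)
    tr = cohort_trace(initial, apply_effectiveness(bundle.markov, e),
                      bundle.econ)
    return (initial.expected_initial_cost + tr.total_cost, tr.total_qalys,
            tr.total_lys, tr.survival)


# ---------------------------------------------------------------------------
# Scenario generator
# ---------------------------------------------------------------------------

#: fixed share of scenario draws forced onto each degenerate corner
P_ZERO_FAILURE = 0.1
P_ZERO_MARKET = 0.1


def _simplex(rng: np.random.Generator, alpha: list[float]) -> np.ndarray:
    row = rng.dirichlet(alpha)
    # exact unit sum despite float rounding
    return row / row.sum()


def generate_scenario(rng: np.random.Generator) -> ParameterBundle:
    """One random, always-valid parameter bundle."""
    tree_row = _simplex(rng, [1.0, 2.0, 30.0, 0.5, 3.0, 3.0])
    tree = TreeParameters(
        p_death_procedure=tree_row[0], p_death_maturation=tree_row[1],
        p_mature_functional=tree_row[2], p_death_nonmaturation=tree_row[3],
        p_cvc_nonmaturation=tree_row[4],
        p_functional_after_intervention=tree_row[5],
        cost_placement=10 ** rng.uniform(3.0, 4.0),
        cost_revision=10 ** rng.uniform(3.0, 4.0),
        cost_cvc_placement=10 ** rng.uniform(2.5, 3.5),
    )

    # monthly death rates ordered as the health states are: a failed graft
    # or catheter never protects against death
    d_func = rng.uniform(0.002, 0.03)
    d_fail = min(d_func * rng.uniform(1.0, 8.0), 0.3)
    d_cvc = min(d_func * rng.uniform(1.0, 5.0), 0.3)
    stay_share = rng.uniform(0.85, 0.99)  # of the surviving functional mass
    p_ff = (1 - d_func) * stay_share
    p_fx = (1 - d_func) * (1 - stay_share)
    if rng.random() < P_ZERO_FAILURE:
        p_ff, p_fx = p_ff + p_fx, 0.0
    x_row = (1 - d_fail) * _simplex(rng, [6.0, 3.0, 1.5])
    u_func = rng.uniform(0.5, 0.9)
    markov = MarkovParameters(
        p_functional_to_functional=p_ff,
        p_functional_to_failed=p_fx,
        p_functional_to_dead=d_func,
        p_failed_to_functional=x_row[0], p_failed_to_failed=x_row[1],
        p_failed_to_cvc=x_row[2], p_failed_to_dead=d_fail,
        p_cvc_to_cvc=1 - d_cvc, p_cvc_to_dead=d_cvc,
        utility_functional=float(u_func),
        utility_failed=float(rng.uniform(0.3, u_func)),
        utility_cvc=float(rng.uniform(0.3, u_func)),
        cost_failed_monthly=10 ** rng.uniform(2.0, 3.2),
        cost_cvc_monthly=10 ** rng.uniform(2.5, 3.7),
    )

    econ = EconSettings(annual_discount_rate=float(rng.uniform(0.0, 0.06)))

    n_stages = 6
    durations = rng.integers(1, 4, size=n_stages)
    starts = np.concatenate([[0], np.cumsum(durations[:-1])])
    stages = [
        DevelopmentStage(
            name=f"Stage {k + 1}",
            cost=10 ** rng.uniform(6.5, 7.8),
            p_success=float(rng.uniform(0.3, 0.95)),
            duration_years=float(durations[k]),
            start_elapsed_years=float(starts[k]),
        )
        for k in range(n_stages)
    ]
    dev_end = int(starts[-1] + durations[-1])

    base_year = 2023
    zero_market = rng.random() < P_ZERO_MARKET
    pen = rng.uniform(0.05, 0.2)
    step = rng.uniform(0.05, 0.2)
    cap = rng.uniform(0.5, 0.9)
    years = []
    size = rng.uniform(5_000, 30_000)
    for k in range(10):
        years.append(MarketYear(
            year=base_year + dev_end + k,
            market_size=0.0 if zero_market else size * (1 + 0.005 * k),
            penetration=float(min(pen + step * k, cap)),
        ))
    market = MarketForecast(years=years)

    commercial = CommercialSettings(
        cogs_per_unit=10 ** rng.uniform(1.5, 2.5),
        sga_fraction_of_revenue=float(rng.uniform(0.1, 0.5)),
        ococ_discount_rate=float(rng.uniform(0.06, 0.15)),
        base_year=base_year,
    )
    return ParameterBundle(tree=tree, markov=markov, econ=econ,
                           stages=stages, market=market,
                           commercial=commercial)


def generate_scenarios(n: int, seed: int) -> list[ParameterBundle]:
    """``n`` reproducible random bundles, each passing validation."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return [require_valid(generate_scenario(rng)) for _ in range(n)]
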