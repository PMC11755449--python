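# Methods

This note documents the modeling choices, default parameters, and numerical
conventions used by `smartavg`. It is written as a self-contained description
of what the code computes; the authoritative definitions are the functions in
`src/smartavg/`.

## 1. Decision problem

A biosensor-integrated arteriovenous graft ("smart AVG") monitors graft
patency and intervenes before thrombotic failure. Its clinical value is the
reduction in graft-failure events; its commercial value is the risk-adjusted
net present value (rNPV) of developing and selling it. The package links the
two: the cost–utility model produces a headroom price per unit of sensor
effectiveness, and the rNPV model values the venture at that price.

## 2. Decision tree (placement and maturation)

Incident patients receive an AVG and pass through six mutually exclusive
placement paths: death during the procedure, death during maturation,
successful maturation, death after non-maturation, permanent CVC after
non-maturation, and function restored after an intervention for
non-maturation. The tree yields:

- an entry distribution over the Markov states (*functional*, *CVC*, *dead*;
  no path enters *failed*), and
- an expected up-front cost: every patient incurs the placement cost,
  non-maturing paths add a revision cost, and the CVC path adds a CVC
  placement cost.

Default path probabilities (summing to 1): 0.022, 0.054, 0.772, 0.011,
0.065, 0.076. Default costs (USD): placement 4,641.19; revision 4,593.26;
CVC placement 896.97. Whether the tree's CVC patients enter the Markov model
in the CVC state (default) or are treated as absorbing is controlled by
`EconSettings.tree_cvc_enters_markov`.

The entry distribution is renormalized onto the probability simplex before
the cohort run to remove accumulated floating-point drift.

## 3. Markov cohort model

Four states — *functional* (F), *failed* (X), *CVC* (C), *dead* (D) — in
monthly cycles over a 60-cycle (five-year) horizon. Default monthly
transition probabilities:

| from \ to   | F     | X     | C     | D     |
|-------------|-------|-------|-------|-------|
| functional  | 0.932 | 0.057 | 0     | 0.011 |
| failed      | 0.533 | 0.280 | 0.120 | 0.067 |
| CVC         | 0     | 0     | 0.974 | 0.026 |
| dead        | 0     | 0     | 0     | 1     |

Default state utilities: functional 0.6839, failed 0.5939, CVC 0.6526
(QALY weights, dimensionless). Default monthly state costs (USD):
functional 647.62, CVC 2,730.18; the failed state is transient and carries
its cost through the functional/CVC costs of its destination cycles.

**Effectiveness.** The sensor is a single multiplier on graft failure:
p(F→X | smart) = (1 − *e*) · p(F→X | standard), with the released mass added
to p(F→F). `apply_effectiveness` rejects *e* outside [0, 1]. All other rows
are identical across arms, so at *e* = 0 the arms coincide and INMB(0) = 0
exactly.

**Accrual and discounting conventions.** Two flags in `EconSettings`:

- `accrual`: `start` (default), `end`, or `half` — whether cycle *t*'s
  occupancy is rewarded with the state entered at the start of the cycle,
  the end, or the midpoint average.
- `discounting`: `annual` (default) applies the yearly factor
  (1 + r)^(−⌊(t − 1)/12⌋), i.e. a step function that discounts all twelve
  cycles of a model year by the same factor; `monthly` applies the smooth
  (1 + r)^(−t/12).

The defaults (start-of-cycle accrual with annual-step discounting) are the
package's base-case convention; the alternates are provided because the
choice moves five-year discounted totals by a few hundred dollars per
patient, which matters when headroom prices are quoted to the dollar.
Default discount rate 3% per year; willingness to pay λ = \$100,000/QALY.

**Outputs.** `run_cua(bundle, e)` returns per-patient discounted cost, QALYs
and life-years for both arms, their increments, and
INMB = λ·ΔQALY − ΔCost (an identity by construction, asserted in tests).
Both arms share the same decision-tree cost, so it cancels from all
increments. The **failure burden** is defined as the negated incrementals at
*e* = 1: the life-years, QALYs and dollars a patient loses to graft failure
under the standard of care over the model horizon.

## 4. rNPV of the development program

Six default stage gates (costs in USD, start in years elapsed from the 2023
base year, probability of success):

| stage                  | cost        | start | p(success) |
|------------------------|-------------|-------|------------|
| concept/feasibility    | 12,277,791  | 0     | 0.7775     |
| design freeze          | 11,050,012  | 3     | 0.7775     |
| verification           | 13,505,570  | 5     | 0.7775     |
| safety/animal study    | 11,050,012  | 6     | 0.48       |
| pivotal clinical trial | 50,338,943  | 7     | 0.757      |
| regulatory & launch    | 17,188,907  | 10    | 0.805      |

Each stage's cost enters as a lump at its start year, weighted by the
probability of *reaching* it (the product of the preceding stages' success
probabilities); the first stage is reached with probability 1. Sales start
after development completes (2035) and run ten years; each year's net cash
flow units · ((1 − SG&A) · price − COGS) is weighted by the cumulative
probability of full approval (0.1375 at the defaults, to four decimals).
Units are market size × penetration, kept **unrounded** in all cash-flow
arithmetic (rounding is display-only). Defaults: COGS \$100/unit, SG&A 30%
of revenue, opportunity cost of capital 10.4%, penetration ramp
15% → 75% in five years then flat.

All flows are discounted to the 2023 base year with exponent
(year − base_year). `rnpv_at_effectiveness(bundle, e)` prices the unit at
max(INMB(*e*), 0): a negative clinical headroom is treated as "no viable
price", not as paying customers to take the device.
`breakeven_effectiveness` scans integer percents 1–100 and returns the first
*e* with strictly positive rNPV (ties in favor of the lower percent); it
returns `None` if no scan point is positive.

## 5. Two-way sensitivity

The grid varies cumulative approval probability *X* ∈ [0, 1] and
effectiveness *e* jointly. A single auxiliary *y* = *X*^(1/8) drives all
gates: stage cost weights are *y*⁰, *y*¹, *y*², *y*³, *y*⁶, *y*⁷ (the
safety study is treated as three probability-only sub-gates, so its
exponents jump from 3 to 6, with the full stage cost carried at *y*³), and
the sales weight is *y*⁸ = *X*. At *X* = 0 only the unweighted first-stage
cost survives, so the entire row equals its negation. Prices are the
INMB(*e*) headroom prices, computed once per column. Columns are not
monotone in *X* in general: at moderate prices the stage-cost weights grow
faster than the risk-weighted sales near small *X*, so the rNPV dips before
rising.

## 6. Microsimulation oracle

`microsimulate(bundle, e, n, seed)` is an independent patient-level
implementation used to cross-check the cohort engine. Each patient owns one
row of a pre-generated (n, 61) uniform array — results are therefore
invariant to iteration order — with column 0 deciding the decision-tree path
(inverse-CDF over the path probabilities) and columns 1–60 the monthly
transitions (cumulative-probability comparison against the patient's current
row of the transition matrix). Accrual and discounting mirror the cohort
flags exactly, so in degenerate deterministic chains the microsimulation
reproduces the cohort values to machine precision, and in the stochastic
base case it agrees within Monte-Carlo error (asserted at four standard
errors in tests and in `scripts/acceptance.py`).

## 7. Scenario generator

`generate_scenarios(n, seed)` emulates the *family* of plausible model
instances — not any specific published population — for property testing:

- monthly death rates: functional ~ U(0.002, 0.03); failed and CVC are the
  functional rate scaled up by U(1, 8) and U(1, 5) (capped at 0.3), encoding
  the clinical ordering that access failure and catheter dependence carry
  excess mortality;
- functional row: stay-share U(0.85, 0.99), remainder split to failure;
  failed row: survival mass split Dirichlet(6, 3, 1.5) over
  (return-to-function, stay-failed, CVC);
- utilities: functional ~ U(0.5, 0.9); failed and CVC ~ U(0.3, u_functional),
  encoding that the functional state is weakly preferred;
- costs, stage schedules (always six gates), and a market forecast whose
  first sales year never precedes the end of development;
- degenerate corners with 10% probability each: zero failure rate
  (INMB ≡ 0) and an all-zero market.

The ordering constraints are what make INMB strictly increasing in
effectiveness across scenarios; without them, pathological parameter sets
(e.g. a CVC state preferred to function) can invert the sign of the
sensor's value, which is a property of those parameters, not a bug. The
generator does **not** emulate correlations between costs and utilities,
time-varying transition rates, competing devices, or parameter uncertainty
distributions suitable for probabilistic sensitivity analysis.

## 8. Validation and numerical conventions

- `validate(bundle)` returns a list of human-readable violations
  (utilities in [0, 1], non-negative costs and prices, probability rows on
  the simplex, sales not preceding development, etc.); `require_valid`
  raises on any. Simplex sums are checked with tolerance 5 × 10⁻³ for
  user-supplied values (accommodating rounded published inputs) and 10⁻⁹
  for internally computed distributions.
- Config files (YAML/JSON) are deep-merged over the defaults, so a partial
  override file touches only the listed fields. `probability_unit: percent`
  rescales all probability-valued fields by 1/100 on load.
- Currency is formatted to two decimals only at the display layer; all
  arithmetic uses full precision.

## 9. Limitations

- Single deterministic base case: no probabilistic sensitivity analysis or
  value-of-information machinery.
- Five-year (60-cycle) horizon; no extrapolation beyond it, so lifetime
  QALY effects are truncated.
- One opportunity cost of capital across all development stages; no
  stage-specific risk premia.
- The effectiveness multiplier acts only on the functional→failed
  transition; sensor effects on maturation, CVC conversion, or mortality are
  out of scope.
- Market forecast is exogenous (no price elasticity or competitor entry).
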