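"""Model inputs as validated types, the default parameter set, and config IO.

The parameter bundle has six sections:

* ``tree`` -- terminal path probabilities and one-time costs of the
  initial-placement decision tree (shared by both arms).
* ``markov`` -- monthly transition probabilities, annual state utilities and
  monthly state costs of the four-state model
  (functional / failed / CVC / dead).
* ``econ`` -- discounting and accrual conventions of the cost-utility
  analysis, the willingness-to-pay threshold, and the horizon.
* ``stages`` -- the ordered development/approval schedule with stage costs,
  success probabilities, durations and elapsed start times.
* ``market`` -- per-year market sizes and penetration for the sales window.
* ``commercial`` -- unit COGS, SG&A fraction, cost of capital, base year.

All probabilities are stored as decimals.  Config files may declare
``probability_unit: percent`` at the top level, in which case every
probability-valued field (tree paths, Markov rows, stage success
probabilities, market penetration) is divided by 100 on load.

Domain rules are checked by :func:`validate`, which reports violations as
data rather than exceptions so that a whole file's problems can be listed at
once.  :func:`load_config` raises on any violation.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Any, Literal

import yaml
from pydantic import BaseModel, ConfigDict

#: simplex tolerance for user-supplied probability rows (inputs are often
#: printed to 3 decimals); computed rows are held to SIMPLEX_TOL_COMPUTED.
SIMPLEX_TOL_USER = 5e-3
SIMPLEX_TOL_COMPUTED = 1e-9

#: canonical state order of the Markov model.
STATES = ("functional", "failed", "cvc", "dead")


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TreeParameters(_Model):
    """Terminal path probabilities and one-time costs of the placement tree.

    The six probabilities are *path* (not branch-conditional) probabilities
    and sum to 1.  Costs are 2023 USD per patient.
    """

    p_death_procedure: float = 0.022
    p_death_maturation: float = 0.054
    p_mature_functional: float = 0.772
    p_death_nonmaturation: float = 0.011
    p_cvc_nonmaturation: float = 0.065
    p_functional_after_intervention: float = 0.076
    cost_placement: float = 4641.19
    cost_revision: float = 4593.26
    cost_cvc_placement: float = 896.97

    @property
    def path_probabilities(self) -> tuple[float, ...]:
        return (
            self.p_death_procedure,
            self.p_death_maturation,
            self.p_mature_functional,
            self.p_death_nonmaturation,
            self.p_cvc_nonmaturation,
            self.p_functional_after_intervention,
        )


class MarkovParameters(_Model):
    """Monthly transition probabilities, utilities and monthly state costs.

    Utilities are annual weights in [0, 1] (dead = 0); QALY accrual per
    monthly cycle is utility / 12.  Only the failed and CVC states carry
    monthly running costs.
    """

    p_functional_to_functional: float = 0.932
    p_functional_to_failed: float = 0.057
    p_functional_to_dead: float = 0.011
    p_failed_to_functional: float = 0.533
    p_failed_to_failed: float = 0.280
    p_failed_to_cvc: float = 0.120
    p_failed_to_dead: float = 0.067
    p_cvc_to_cvc: float = 0.974
    p_cvc_to_dead: float = 0.026
    utility_functional: float = 0.6839
    utility_failed: float = 0.5939
    utility_cvc: float = 0.6526
    cost_failed_monthly: float = 647.62
    cost_cvc_monthly: float = 2730.18

    def rows(self) -> dict[str, tuple[float, ...]]:
        """Outgoing probabilities per transient state (dead is absorbing)."""
        return {
            "functional": (
                self.p_functional_to_functional,
                self.p_functional_to_failed,
                self.p_functional_to_dead,
            ),
            "failed": (
                self.p_failed_to_functional,
                self.p_failed_to_failed,
                self.p_failed_to_cvc,
                self.p_failed_to_dead,
            ),
            "cvc": (self.p_cvc_to_cvc, self.p_cvc_to_dead),
        }


class EconSettings(_Model):
    """Economic settings and convention flags of the cost-utility analysis.

    ``accrual`` picks the occupancy that earns each cycle's cost/utility:
    ``start`` (state at the beginning of the cycle), ``end`` (state after the
    cycle's transition) or ``half`` (average of the two, i.e. a half-cycle
    correction).  ``discounting`` is ``annual`` (step discounting by calendar
    year of the cycle) or ``monthly`` (smooth per-cycle factor
    ``(1+r)**(-m/12)``).  The defaults, start-of-cycle accrual with annual
    step discounting, are the conventions of a year-blocked spreadsheet
    cohort model and reproduce the reference results most closely.
    """

    annual_discount_rate: float = 0.03
    wtp_lambda: float = 100_000.0
    horizon_cycles: int = 60
    cycle_length_months: int = 1
    accrual: Literal["start", "end", "half"] = "start"
    discounting: Literal["annual", "monthly"] = "annual"
    tree_cvc_enters_markov: bool = True


class Effectiveness(_Model):
    """Proportional reduction of the functional->failed monthly probability."""

    e: float = 0.0


class DevelopmentStage(_Model):
    """One development/approval stage: cost lump, success probability, timing."""

    name: str
    cost: float
    p_success: float
    duration_years: float
    start_elapsed_years: float


class CommercialSettings(_Model):
    """Commercial assumptions of the risk-adjusted NPV model."""

    cogs_per_unit: float = 100.0
    sga_fraction_of_revenue: float = 0.30
    ococ_discount_rate: float = 0.104
    base_year: int = 2023


class MarketYear(_Model):
    year: int
    market_size: float
    penetration: float

    @property
    def forecast_units(self) -> float:
        """Units sold = size x penetration, carried unrounded."""
        return self.market_size * self.penetration


class MarketForecast(_Model):
    years: list[MarketYear]

    @property
    def calendar_years(self) -> list[int]:
        return [y.year for y in self.years]

    @property
    def units(self) -> list[float]:
        return [y.forecast_units for y in self.years]


class ParameterBundle(_Model):
    """The full input set of the linked CUA + rNPV model."""

    tree: TreeParameters = TreeParameters()
    markov: MarkovParameters = MarkovParameters()
    econ: EconSettings = EconSettings()
    stages: list[DevelopmentStage]
    market: MarketForecast
    commercial: CommercialSettings = CommercialSettings()


# ---------------------------------------------------------------------------
# Defaults (2023 USD; base-case analysis)
# ---------------------------------------------------------------------------

# First three stage probabilities are 0.7775 (displayed as 77.8% in some
# summaries): 0.7775**3 = 0.470, the cumulative probability at the IDE stage,
# and the full product is the base-case cumulative 13.75%.
_DEFAULT_STAGES = [
    ("Concept Development", 12_277_791.0, 0.7775, 3, 0),
    ("Clinical Unit Development", 11_050_012.0, 0.7775, 2, 3),
    ("IDE Application", 13_505_570.0, 0.7775, 1, 5),
    ("Clinical Safety Study", 11_050_012.0, 0.48, 1, 6),
    ("Pivotal Clinical Trial", 50_338_943.0, 0.757, 3, 7),
    ("PMA Approval Process", 17_188_907.0, 0.805, 2, 10),
]

# Market sizes (AVG placements/year) with penetration 15% in the launch year
# rising 15 points/year to a 75% cap.
_DEFAULT_MARKET = [
    (2035, 21_195, 0.15),
    (2036, 21_300, 0.30),
    (2037, 21_403, 0.45),
    (2038, 21_504, 0.60),
    (2039, 21_602, 0.75),
    (2040, 21_698, 0.75),
    (2041, 21_793, 0.75),
    (2042, 21_885, 0.75),
    (2043, 21_976, 0.75),
    (2044, 22_066, 0.75),
]


def default_parameters() -> ParameterBundle:
    """The base-case parameter bundle (2023 USD)."""
    return ParameterBundle(
        stages=[
            DevelopmentStage(
                name=n, cost=c, p_success=p,
                duration_years=d, start_elapsed_years=s,
            )
            for n, c, p, d, s in _DEFAULT_STAGES
        ],
        market=MarketForecast(
            years=[
                MarketYear(year=y, market_size=m, penetration=p)
                for y, m, p in _DEFAULT_MARKET
            ]
        ),
    )


def bundled_fixture_path() -> Path:
    """Path of the packaged base-case config file."""
    return Path(str(resources.files("smartavg") / "data" / "base_case_2023.yaml"))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _check_simplex(violations: list[str], label: str,
                   row: tuple[float, ...], tol: float) -> None:
    for v in row:
        if not 0.0 <= v <= 1.0:
            violations.append(f"{label}: probability {v} outside [0, 1]")
    if abs(sum(row) - 1.0) > tol:
        violations.append(
            f"{label}: probabilities sum to {sum(row):.6f}, expected 1 "
            f"within {tol}"
        )


def validate(bundle: ParameterBundle,
             tol: float = SIMPLEX_TOL_USER) -> list[str]:
    """Check every domain rule; return violations as human-readable strings.

    An empty list means the bundle is valid.  ``tol`` is the simplex
    tolerance applied to probability rows (use
    :data:`SIMPLEX_TOL_COMPUTED` for rows produced by computation).
    """
    v: list[str] = []
    t = bundle.tree
    _check_simplex(v, "tree path probabilities", t.path_probabilities, tol)
    for name in ("cost_placement", "cost_revision", "cost_cvc_placement"):
        if getattr(t, name) < 0:
            v.append(f"tree.{name}: cost must be >= 0")

    m = bundle.markov
    for state, row in m.rows().items():
        _check_simplex(v, f"markov row '{state}'", row, tol)
    for name in ("utility_functional", "utility_failed", "utility_cvc"):
        u = getattr(m, name)
        if not 0.0 <= u <= 1.0:
            v.append(f"markov.{name}: utility {u} outside [0, 1]")
    for name in ("cost_failed_monthly", "cost_cvc_monthly"):
        if getattr(m, name) < 0:
            v.append(f"markov.{name}: cost must be >= 0")

    e = bundle.econ
    if e.annual_discount_rate < 0:
        v.append("econ.annual_discount_rate: must be >= 0")
    if e.wtp_lambda <= 0:
        v.append("econ.wtp_lambda: must be > 0")
    if e.horizon_cycles < 1:
        v.append("econ.horizon_cycles: must be >= 1")

    if not bundle.stages:
        v.append("stages: schedule must contain at least one stage")
    prev_start = None
    for s in bundle.stages:
        if s.cost < 0:
            v.append(f"stages[{s.name}].cost: must be >= 0")
        if not 0.0 <= s.p_success <= 1.0:
            v.append(f"stages[{s.name}].p_success: {s.p_success} outside [0, 1]")
        if prev_start is not None and s.start_elapsed_years < prev_start:
            v.append(
                f"stages[{s.name}].start_elapsed_years: start times must be "
                "non-decreasing"
            )
        prev_start = s.start_elapsed_years

    prev_pen = None
    for y in bundle.market.years:
        if not 0.0 <= y.penetration <= 1.0:
            v.append(f"market[{y.year}].penetration: outside [0, 1]")
        if y.market_size < 0:
            v.append(f"market[{y.year}].market_size: must be >= 0")
        if prev_pen is not None and y.penetration < prev_pen - 1e-12:
            v.append(f"market[{y.year}].penetration: schedule must be "
                     "non-decreasing")
        prev_pen = y.penetration

    c = bundle.commercial
    if not 0.0 <= c.sga_fraction_of_revenue < 1.0:
        v.append("commercial.sga_fraction_of_revenue: must be in [0, 1)")
    if c.ococ_discount_rate <= 0:
        v.append("commercial.ococ_discount_rate: must be > 0")
    if bundle.stages and bundle.market.years:
        dev_end = bundle.commercial.base_year + max(
            s.start_elapsed_years + s.duration_years for s in bundle.stages
        )
        first_sale = min(bundle.market.calendar_years)
        if first_sale < dev_end:
            v.append(
                f"market: first sales year {first_sale} precedes development "
                f"completion ({dev_end:g})"
            )
    return v


def require_valid(bundle: ParameterBundle,
                  tol: float = SIMPLEX_TOL_USER) -> ParameterBundle:
    """Raise ``ValueError`` listing all violations if the bundle is invalid."""
    problems = validate(bundle, tol=tol)
    if problems:
        raise ValueError("invalid parameter bundle:\n  " + "\n  ".join(problems))
    return bundle


# ---------------------------------------------------------------------------
# Config IO
# ---------------------------------------------------------------------------

_PROBABILITY_FIELDS = {
    "tree": [f for f in TreeParameters.model_fields if f.startswith("p_")],
    "markov": [f for f in MarkovParameters.model_fields if f.startswith("p_")],
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], val)
        else:
            out[k] = val
    return out


def _rescale_percent(data: dict[str, Any]) -> dict[str, Any]:
    data = json.loads(json.dumps(data))  # deep copy
    for section, fields in _PROBABILITY_FIELDS.items():
        for f in fields:
            if f in data.get(section, {}):
                data[section][f] /= 100.0
    for s in data.get("stages", []):
        if "p_success" in s:
            s["p_success"] /= 100.0
    for y in data.get("market", {}).get("years", []):
        if "penetration" in y:
            y["penetration"] /= 100.0
    return data


def bundle_to_dict(bundle: ParameterBundle) -> dict[str, Any]:
    return bundle.model_dump(mode="json")


def save_config(bundle: ParameterBundle, path: str | Path) -> None:
    """Write a bundle as YAML (``.yaml``/``.yml``) or JSON (anything else)."""
    path = Path(path)
    data = bundle_to_dict(bundle)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def load_config(path: str | Path) -> ParameterBundle:
    """Load a YAML/JSON config; omitted scalars fall back to the defaults.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` naming
    every violated field/rule for an invalid one.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") \
        else json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    unit = data.pop("probability_unit", "decimal")
    if unit == "percent":
        data = _rescale_percent(data)
    elif unit != "decimal":
        raise ValueError(f"{path}: probability_unit must be 'decimal' or "
                         f"'percent', got {unit!r}")
    defaults = bundle_to_dict(default_parameters())
    # stages/market lists replace wholesale; scalar sections merge.
    merged = _deep_merge(defaults, data)
    bundle = ParameterBundle.model_validate(merged)
    return require_valid(bundle)


def parameters_table(bundle: ParameterBundle) -> "pd.DataFrame":
    """Flat (section, field, value) view of a bundle, for CSV export."""
    import pandas as pd

    rows = []
    for section in ("tree", "markov", "econ", "commercial"):
        obj = getattr(bundle, section)
        for field, value in obj.model_dump().items():
            rows.append((section, field, value))
    for i, s in enumerate(bundle.stages):
        for field, value in s.model_dump().items():
            rows.append((f"stages[{i}]", field, value))
    for y in bundle.market.years:
        rows.append(("market", f"{y.year}.market_size", y.market_size))
        rows.append(("market", f"{y.year}.penetration", y.penetration))
    return pd.DataFrame(rows, columns=["section", "field", "value"])
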