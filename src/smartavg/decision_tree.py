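"""Initial-placement decision tree.

Both arms share the same tree: implantation outcomes are assumed independent
of the graft's biosensor, so the tree contributes an identical starting state
distribution and one-time expected cost to each arm.  All tree events occur
instantaneously at t = 0, undiscounted and with no QALY accrual; incremental
results are therefore invariant to every tree parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import (
    SIMPLEX_TOL_COMPUTED,
    TreeParameters,
)


@dataclass(frozen=True)
class InitialDistribution:
    """Cohort split at tree exit plus the expected one-time cost per patient."""

    share_functional: float
    share_cvc: float
    share_dead: float
    expected_initial_cost: float

    def __post_init__(self) -> None:
        total = self.share_functional + self.share_cvc + self.share_dead
        if abs(total - 1.0) > SIMPLEX_TOL_COMPUTED:
            raise ValueError(f"initial shares sum to {total}, expected 1")
        if min(self.share_functional, self.share_cvc, self.share_dead) < 0:
            raise ValueError("initial shares must be non-negative")


def tree_outcomes(tree: TreeParameters) -> InitialDistribution:
    """Collapse the placement tree into a starting distribution and cost.

    Functional entrants are patients whose graft matured plus those restored
    by revision after non-maturation.  Every non-maturing patient (whether
    later functional, switched to a CVC, or dead) incurs the revision cost;
    CVC placement is additionally charged on the CVC path.
    """
    p = tree.path_probabilities
    if any(x < 0 or x > 1 for x in p) or abs(sum(p) - 1.0) > 5e-3:
        raise ValueError("tree path probabilities must lie in [0,1] and sum to 1")
    share_functional = (
        tree.p_mature_functional + tree.p_functional_after_intervention
    )
    share_cvc = tree.p_cvc_nonmaturation
    share_dead = (
        tree.p_death_procedure
        + tree.p_death_maturation
        + tree.p_death_nonmaturation
    )
    # renormalize away print-precision slack so downstream simplex checks
    # hold to machine precision
    total = share_functional + share_cvc + share_dead
    p_nonmaturation = (
        tree.p_functional_after_intervention
        + tree.p_cvc_nonmaturation
        + tree.p_death_nonmaturation
    )
    expected_cost = (
        tree.cost_placement
        + p_nonmaturation * tree.cost_revision
        + tree.p_cvc_nonmaturation * tree.cost_cvc_placement
    )
    return InitialDistribution(
        share_functional=share_functional / total,
        share_cvc=share_cvc / total,
        share_dead=share_dead / total,
        expected_initial_cost=expected_cost,
    )
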