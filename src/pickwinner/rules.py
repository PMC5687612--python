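"""Winner decision calculus for a completed two-arm trial.

An arm's fate is one of ``fail_stage1`` / ``fail_stage2`` / ``pass``; the
winner rule maps the pair of fates to a declaration:

* both non-pass: no winner ("both losers");
* exactly one pass: that arm wins outright, no probability computed;
* both pass ("competitive"): arm B wins if ``Pr(B > A) > delta``, arm A wins
  if ``Pr(B > A) < 1 - delta``, otherwise no clear winner.

A Fisher comparator replaces the Bayesian rule with a one-sided exact test at
a given level, used here only as a benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .bayes import PriorSpec, make_priors, posterior_params, prob_beta_greater
from .fisher import TwoByTwo, fisher_one_sided_p
from .simon import SimonDesign

__all__ = ["ArmOutcome", "DecisionRule", "TrialResult", "classify_arm", "pick_winner"]

ArmStatus = Literal["fail_stage1", "fail_stage2", "pass"]


@dataclass(frozen=True)
class ArmOutcome:
    """Observed counts and resulting status for one arm."""

    x1: int
    k: int
    enrolled: int
    status: ArmStatus


@dataclass(frozen=True)
class DecisionRule:
    """Winner threshold, prior, and comparator choice."""

    delta: float = 0.8
    prior: PriorSpec = PriorSpec("noninformative", c=1.0)
    comparator: Literal["bayes", "fisher"] = "bayes"
    fisher_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.5 <= self.delta < 1.0:
            raise ValueError(f"delta must be in [0.5, 1), got {self.delta}")
        if self.comparator not in ("bayes", "fisher"):
            raise ValueError(f"comparator must be 'bayes' or 'fisher', got {self.comparator!r}")
        if self.comparator == "fisher" and not 0.0 < self.fisher_alpha < 1.0:
            raise ValueError(f"fisher_alpha must be in (0, 1), got {self.fisher_alpha}")


@dataclass(frozen=True)
class TrialResult:
    """Joint outcome of both arms with the winner declaration."""

    outcome_A: ArmOutcome
    outcome_B: ArmOutcome
    winner: Literal["A", "B", "none"]
    winner_prob: float | None  # Pr(B > A) when both competitive, else None
    total_sample_size: int


def classify_arm(x1: int, k: int, design: SimonDesign) -> ArmOutcome:
    """Classify one arm's observed counts against its design bounds.

    For a stage-1 stop (``x1 <= r1``) the counts must satisfy ``k == x1``
    and ``enrolled`` is ``n1``; otherwise stage 2 completes with ``n``
    patients and the arm passes iff ``k > r``.
    """
    if not 0 <= x1 <= design.n1:
        raise ValueError(f"need 0 <= x1 <= n1={design.n1}, got x1={x1}")
    if x1 <= design.r1:
        if k != x1:
            raise ValueError(
                f"arm stops at stage 1 when x1={x1} <= r1={design.r1}; "
                f"total k must equal x1, got k={k}"
            )
        return ArmOutcome(x1=x1, k=k, enrolled=design.n1, status="fail_stage1")
    if not x1 <= k <= design.n:
        raise ValueError(f"need x1 <= k <= n={design.n}, got x1={x1}, k={k}")
    if k - x1 > design.n2:
        raise ValueError(f"stage-2 responders k-x1={k - x1} exceed n2={design.n2}")
    status: ArmStatus = "pass" if k > design.r else "fail_stage2"
    return ArmOutcome(x1=x1, k=k, enrolled=design.n, status=status)


def _bayes_prob(outcome_A: ArmOutcome, outcome_B: ArmOutcome, prior: PriorSpec) -> float:
    prior_A, prior_B = make_priors(prior)
    post_A = posterior_params(prior_A, outcome_A.k, outcome_A.enrolled)
    post_B = posterior_params(prior_B, outcome_B.k, outcome_B.enrolled)
    return prob_beta_greater(post_B, post_A)


def pick_winner(
    outcome_A: ArmOutcome, outcome_B: ArmOutcome, rule: DecisionRule
) -> TrialResult:
    """Apply the winner rule to a pair of arm outcomes."""
    total = outcome_A.enrolled + outcome_B.enrolled
    a_pass = outcome_A.status == "pass"
    b_pass = outcome_B.status == "pass"

    if not a_pass and not b_pass:
        return TrialResult(outcome_A, outcome_B, "none", None, total)
    if a_pass != b_pass:
        return TrialResult(outcome_A, outcome_B, "B" if b_pass else "A", None, total)

    if rule.comparator == "fisher":
        t = TwoByTwo(
            kB=outcome_B.k, fB=outcome_B.enrolled - outcome_B.k,
            kA=outcome_A.k, fA=outcome_A.enrolled - outcome_A.k,
        )
        if fisher_one_sided_p(t, "B_greater") < rule.fisher_alpha:
            return TrialResult(outcome_A, outcome_B, "B", None, total)
        if fisher_one_sided_p(t, "A_greater") < rule.fisher_alpha:
            return TrialResult(outcome_A, outcome_B, "A", None, total)
        return TrialResult(outcome_A, outcome_B, "none", None, total)

    prob = _bayes_prob(outcome_A, outcome_B, rule.prior)
    # a knife-edge guard so floating-point noise at Pr == delta (possible only
    # at delta = 0.5 with symmetric counts) cannot decide a winner
    if prob > rule.delta and abs(prob - rule.delta) > 1e-9:
        winner = "B"
    elif prob < 1.0 - rule.delta and abs(prob - (1.0 - rule.delta)) > 1e-9:
        winner = "A"
    else:
        winner = "none"
    return TrialResult(outcome_A, outcome_B, winner, prob, total)
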