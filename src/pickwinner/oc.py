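"""Exact operating characteristics of the two-arm pick-the-winner procedure.

Everything here is computed by enumeration, not simulation.  The two arms run
independent two-stage designs, so the joint distribution over the nine status
cells (each arm in {fail stage 1, fail stage 2, pass}) is a product of
per-arm probabilities, and the both-pass cell decomposes exactly over the
passing total-count pairs ``(kA, kB)`` via the per-arm pass pmf.  The winner
rule is then applied to each passing pair.

Boundary convention: probability mass lying exactly on the decision threshold
(``Pr(B > A) == delta`` to within 1e-9, which with uniform priors and equal
arm sizes happens only for tied counts at ``delta = 0.5``) is split evenly
between the two arms.  At ``delta = 0.5`` the rule is a coin flip on tied
evidence, so half of that mass counts toward each arm's winner probability;
for any ``delta > 0.5`` the convention is inert.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .bayes import PriorSpec, make_priors, posterior_params, prob_beta_greater
from .fisher import TwoByTwo, fisher_one_sided_p
from .rules import DecisionRule
from .simon import SimonDesign, pass_probability, pass_total_pmf, stage1_fail_probability

__all__ = [
    "OperatingChars",
    "exact_operating_characteristics",
    "delta_sweep",
    "fisher_rule_oc",
    "crt_power",
    "prob_vs_difference_map",
]

STATUS_LABELS = ("fail_stage1", "fail_stage2", "pass")

_EDGE_TOL = 1e-9


@dataclass(frozen=True)
class OperatingChars:
    """Joint outcome probabilities of the two-arm procedure.

    ``matrix3x3[i, j]`` is the probability that arm A has status ``i`` and
    arm B status ``j`` in the order (fail stage 1, fail stage 2, pass); the
    cells are unconditional and sum to one.  "Local" winner probabilities are
    joint with the both-pass event; "overall" probabilities add the
    single-pass routes.
    """

    matrix3x3: np.ndarray
    p_both_pass: float
    p_B_winner_overall: float
    p_A_winner_overall: float
    p_B_winner_local: float
    p_A_winner_local: float
    p_no_winner: float

    def matrix_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix3x3,
            index=pd.Index(STATUS_LABELS, name="arm_A"),
            columns=pd.Index(STATUS_LABELS, name="arm_B"),
        )


@lru_cache(maxsize=64)
def _winner_prob_table(
    design_A: SimonDesign, design_B: SimonDesign, prior: PriorSpec
) -> dict[tuple[int, int], float]:
    """``Pr(B > A)`` for every passing total-count pair ``(kA, kB)``."""
    prior_A, prior_B = make_priors(prior)
    out: dict[tuple[int, int], float] = {}
    for kA in range(design_A.r + 1, design_A.n + 1):
        post_A = posterior_params(prior_A, kA, design_A.n)
        for kB in range(design_B.r + 1, design_B.n + 1):
            post_B = posterior_params(prior_B, kB, design_B.n)
            out[(kA, kB)] = prob_beta_greater(post_B, post_A)
    return out


def _local_winner_mass(
    design_A: SimonDesign,
    design_B: SimonDesign,
    pA: float,
    pB: float,
    rule: DecisionRule,
) -> tuple[float, float]:
    """(P(both pass and B wins), P(both pass and A wins)) by enumeration."""
    pmf_A = pass_total_pmf(design_A, pA)
    pmf_B = pass_total_pmf(design_B, pB)
    local_B = local_A = 0.0
    if rule.comparator == "fisher":
        for (kA, wA) in pmf_A.items():
            for (kB, wB) in pmf_B.items():
                w = wA * wB
                if w == 0.0:
                    continue
                t = TwoByTwo(kB=kB, fB=design_B.n - kB, kA=kA, fA=design_A.n - kA)
                if fisher_one_sided_p(t, "B_greater") < rule.fisher_alpha:
                    local_B += w
                elif fisher_one_sided_p(t, "A_greater") < rule.fisher_alpha:
                    local_A += w
        return local_B, local_A

    table = _winner_prob_table(design_A, design_B, rule.prior)
    hi, lo = rule.delta, 1.0 - rule.delta
    for (kA, wA) in pmf_A.items():
        for (kB, wB) in pmf_B.items():
            w = wA * wB
            if w == 0.0:
                continue
            prob = table[(kA, kB)]
            if abs(prob - hi) <= _EDGE_TOL or abs(prob - lo) <= _EDGE_TOL:
                # threshold-boundary mass splits evenly (coin flip at delta=0.5)
                local_B += 0.5 * w
                local_A += 0.5 * w
            elif prob > hi:
                local_B += w
            elif prob < lo:
                local_A += w
    return local_B, local_A


def exact_operating_characteristics(
    design_A: SimonDesign,
    design_B: SimonDesign,
    pA: float,
    pB: float,
    rule: DecisionRule,
) -> OperatingChars:
    """Exact power / type I error decomposition for true rates ``(pA, pB)``.

    The overall probability of declaring B the winner is
    ``P(B passes) P(A fails) + P(both pass and Pr(B > A) > delta)``, and
    symmetrically for A.
    """
    probs = {}
    for arm, (design, p) in {"A": (design_A, pA), "B": (design_B, pB)}.items():
        f1 = stage1_fail_probability(design, p)
        ps = pass_probability(design, p)
        probs[arm] = np.array([f1, 1.0 - f1 - ps, ps])
    matrix = np.outer(probs["A"], probs["B"])

    local_B, local_A = _local_winner_mass(design_A, design_B, pA, pB, rule)
    pass_A, pass_B = probs["A"][2], probs["B"][2]
    both = pass_A * pass_B
    overall_B = pass_B * (1.0 - pass_A) + local_B
    overall_A = pass_A * (1.0 - pass_B) + local_A
    return OperatingChars(
        matrix3x3=matrix,
        p_both_pass=both,
        p_B_winner_overall=overall_B,
        p_A_winner_overall=overall_A,
        p_B_winner_local=local_B,
        p_A_winner_local=local_A,
        p_no_winner=1.0 - overall_B - overall_A,
    )


def delta_sweep(
    design_A: SimonDesign,
    design_B: SimonDesign,
    pA: float,
    pB: float,
    prior: PriorSpec,
    deltas: list[float],
) -> pd.DataFrame:
    """Local winner probabilities across thresholds.

    One row per ``delta`` with the both-pass probability and the local B-win
    probability; under ``pA == pB`` the latter is the local misclassification
    probability (local type I error).
    """
    rows = []
    for d in deltas:
        rule = DecisionRule(delta=d, prior=prior)
        oc = exact_operating_characteristics(design_A, design_B, pA, pB, rule)
        rows.append(
            {
                "delta": d,
                "p_both_pass": oc.p_both_pass,
                "p_B_winner_local": oc.p_B_winner_local,
                "p_A_winner_local": oc.p_A_winner_local,
            }
        )
    return pd.DataFrame(rows)


def fisher_rule_oc(
    design_A: SimonDesign,
    design_B: SimonDesign,
    pA: float,
    pB: float,
    fisher_alpha: float = 0.05,
) -> OperatingChars:
    """Operating characteristics with the one-sided Fisher comparator."""
    rule = DecisionRule(comparator="fisher", fisher_alpha=fisher_alpha)
    return exact_operating_characteristics(design_A, design_B, pA, pB, rule)


def crt_power(
    n_per_arm: int, pA: float, pB: float, alpha_one_sided: float
) -> float:
    """Exact power of a single-stage two-arm trial under the Fisher test.

    Enumerates all ``(kA, kB)`` binomial pairs and rejects (declares B
    superior) when the one-sided Fisher p-value is strictly below
    ``alpha_one_sided``.  The attained size can fall below the nominal level
    because of the discreteness of the test.
    """
    if n_per_arm < 1:
        raise ValueError(f"n_per_arm must be at least 1, got {n_per_arm}")
    from scipy.stats import binom

    ks = np.arange(n_per_arm + 1)
    wA = binom.pmf(ks, n_per_arm, pA)
    wB = binom.pmf(ks, n_per_arm, pB)
    total = 0.0
    for kA in ks:
        for kB in ks:
            w = wA[kA] * wB[kB]
            if w == 0.0:
                continue
            t = TwoByTwo(kB=int(kB), fB=n_per_arm - int(kB), kA=int(kA), fA=n_per_arm - int(kA))
            if fisher_one_sided_p(t, "B_greater") < alpha_one_sided:
                total += w
    return float(total)


def prob_vs_difference_map(
    design: SimonDesign,
    prior: PriorSpec,
    pA: float | None = None,
    pB: float | None = None,
) -> pd.DataFrame:
    """``Pr(B > A)`` against the observed response-rate difference.

    Covers every both-pass count pair ``(kA, kB)`` of two arms running the
    same design; columns ``kA``, ``kB``, ``difference`` (observed rate B
    minus rate A) and ``prob_B_greater``.  When true rates ``(pA, pB)`` are
    given, a ``joint_prob`` column carries each pair's unconditional
    probability.

    On the pairs a trial can realistically produce, the probability varies
    only slightly within a fixed difference, which is what licenses reading
    ``Pr(B > A)`` as a proxy for the difference (0.80 is roughly a 10-point
    difference on the 37-per-arm design).  Pairs with pathologically extreme
    counts (e.g. 35 vs 37 responders) sit far from that trend but carry
    essentially no probability.
    """
    table = _winner_prob_table(design, design, prior)
    rows = [
        {
            "kA": kA,
            "kB": kB,
            "difference": (kB - kA) / design.n,
            "prob_B_greater": prob,
        }
        for (kA, kB), prob in table.items()
    ]
    out = pd.DataFrame(rows)
    if pA is not None and pB is not None:
        pmf_A = pass_total_pmf(design, pA)
        pmf_B = pass_total_pmf(design, pB)
        out["joint_prob"] = [
            pmf_A[kA] * pmf_B[kB] for kA, kB in zip(out["kA"], out["kB"])
        ]
    return out.sort_values(["difference", "kA"]).reset_index(drop=True)
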