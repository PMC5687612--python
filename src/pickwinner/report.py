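"""Protocol-ready statistical-plan text for a two-arm pick-the-winner trial."""

from __future__ import annotations

import io

from .config import TrialPlanConfig
from .oc import exact_operating_characteristics
from .rules import DecisionRule
from .simon import DesignCharacteristics, SimonDesign, search_simon_design

__all__ = ["generate_statistical_plan"]


def _arm_paragraph(label: str, design: SimonDesign, chars: DesignCharacteristics,
                   p0: float, p1: float) -> str:
    return (
        f"Arm {label} uses a Simon {design.kind} two-stage design testing an "
        f"unacceptable response rate of {p0:.0%} against a promising rate of "
        f"{p1:.0%}. {design.n1} patients will be enrolled in the first stage. "
        f"If {design.r1} or fewer respond, the arm will be stopped. Otherwise "
        f"{design.n2} additional patients (a total of {design.n}) will be "
        f"enrolled; the treatment is declared ineffective if the total number "
        f"of responders is {design.r} or less. The design attains a type I "
        f"error of {chars.attained_alpha:.3f}, power {chars.attained_power:.3f}, "
        f"probability of early termination {chars.pet0:.3f} and expected "
        f"sample size {chars.en0:.1f} under the null rate."
    )


def generate_statistical_plan(cfg: TrialPlanConfig) -> str:
    """Compose the statistical-plan narrative, winner rule, sample-size
    bounds and per-scenario operating characteristics for a config."""
    designA, charsA = search_simon_design(cfg.hypothesis_A, cfg.kind)
    designB, charsB = search_simon_design(cfg.hypothesis_B, cfg.kind)
    rule = DecisionRule(delta=cfg.delta, prior=cfg.prior)

    buf = io.StringIO()
    w = buf.write
    w("STATISTICAL PLAN: Bayesian pick-the-winner randomized phase II design\n")
    w("=" * 70 + "\n\n")
    w("Design\n------\n")
    w("Patients are randomized between two arms, each evaluated by its own "
      "Simon two-stage futility design.\n\n")
    w(_arm_paragraph("A", designA, charsA, cfg.hypothesis_A.p0, cfg.hypothesis_A.p1) + "\n\n")
    if (designB, cfg.hypothesis_B) == (designA, cfg.hypothesis_A):
        w("Arm B uses the same design.\n\n")
    else:
        w(_arm_paragraph("B", designB, charsB, cfg.hypothesis_B.p0, cfg.hypothesis_B.p1) + "\n\n")

    w("Winner rule\n-----------\n")
    w(
        f"An arm passing its second stage is competitive. If only one arm is "
        f"competitive, it is the winner. If both arms are competitive, the "
        f"posterior probability Pr(B > A) of a higher response rate in arm B "
        f"is computed from independent beta posteriors under the "
        f"{cfg.prior.label()} prior. Arm B is the winner if Pr(B > A) > "
        f"{cfg.delta:g}; arm A is the winner if Pr(B > A) < {1 - cfg.delta:g}; "
        f"otherwise no clear winner is declared. On designs of this size a "
        f"threshold of {cfg.delta:g} corresponds to roughly a "
        f"{(cfg.delta - 0.5) / 3:.0%} observed response-rate difference.\n\n"
    )

    min_n = designA.n1 + designB.n1
    mixed = min(designA.n1 + designB.n, designA.n + designB.n1)
    max_n = designA.n + designB.n
    w("Sample size\n-----------\n")
    w(
        f"The total sample size is {min_n} if both arms stop at the first "
        f"stage, {mixed} if exactly one arm stops at the first stage, and "
        f"{max_n} if both arms complete the second stage.\n\n"
    )

    if cfg.scenarios:
        w("Operating characteristics\n-------------------------\n")
        for pA, pB in cfg.scenarios:
            oc = exact_operating_characteristics(designA, designB, pA, pB, rule)
            w(f"Scenario: true response rates {pB:.0%} (B) vs {pA:.0%} (A)\n")
            w(oc.matrix_frame().round(4).to_string() + "\n")
            w(
                f"  Both arms competitive: {oc.p_both_pass:.2%}; among these, "
                f"arm B is declared winner with probability {oc.p_B_winner_local:.2%}.\n"
                f"  Overall probability of declaring arm B the winner: "
                f"{oc.p_B_winner_overall:.0%}; arm A: {oc.p_A_winner_overall:.0%}; "
                f"no winner: {oc.p_no_winner:.0%}.\n\n"
            )
    return buf.getvalue()
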