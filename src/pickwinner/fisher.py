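"""One-sided Fisher exact test on a 2x2 response table, and Altham's identity.

The test conditions on both margins: with ``kB`` responders of ``nB`` in arm B
and ``kA`` of ``nA`` in arm A, the one-sided p-value in B's direction is the
hypergeometric tail ``P(X >= kB)`` with
``X ~ Hypergeom(nA + nB, kA + kB, nB)``, including the observed table.

Altham (1969): with the improper prior pair Beta(1, 0) in arm A and
Beta(0, 1) in arm B — the pair maximally unfavorable to arm B — the posterior
probability ``Pr(B > A)`` equals one minus this one-sided p-value, so the
Bayesian rule under that prior reproduces the Fisher test exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from scipy.stats import hypergeom

from .bayes import BetaParams, prob_beta_greater

__all__ = ["TwoByTwo", "fisher_one_sided_p", "altham_identity_check"]

Direction = Literal["B_greater", "A_greater"]


@dataclass(frozen=True)
class TwoByTwo:
    """Responder / non-responder counts per arm."""

    kB: int
    fB: int
    kA: int
    fA: int

    def __post_init__(self) -> None:
        if min(self.kB, self.fB, self.kA, self.fA) < 0:
            raise ValueError("all cell counts must be nonnegative")
        if self.kB + self.fB == 0 or self.kA + self.fA == 0:
            raise ValueError("each arm needs at least one subject")

    @property
    def nB(self) -> int:
        return self.kB + self.fB

    @property
    def nA(self) -> int:
        return self.kA + self.fA


def fisher_one_sided_p(t: TwoByTwo, direction: Direction = "B_greater") -> float:
    """One-sided Fisher exact p-value, observed table included in the tail."""
    total = t.nA + t.nB
    k_total = t.kA + t.kB
    if k_total == 0 or k_total == total:
        # margins carry no information about direction
        return 1.0
    if direction == "B_greater":
        return float(hypergeom.sf(t.kB - 1, total, k_total, t.nB))
    if direction == "A_greater":
        return float(hypergeom.cdf(t.kB, total, k_total, t.nB))
    raise ValueError(f"direction must be 'B_greater' or 'A_greater', got {direction!r}")


def altham_identity_check(t: TwoByTwo) -> tuple[float, float, float]:
    """``(Pr(B > A) under the unfavorable c=1 prior, one-sided p, discrepancy)``.

    The unfavorable pair at ``c = 1`` gives posteriors ``Beta(kA + 1, fA)``
    for arm A and ``Beta(kB, fB + 1)`` for arm B; properness requires
    ``kB >= 1`` and ``fA >= 1``.  The discrepancy
    ``|Pr(B > A) + p_{B_greater} - 1|`` is zero in exact arithmetic.
    """
    if t.kB < 1 or t.fA < 1:
        raise ValueError(
            "unfavorable c=1 posterior needs kB >= 1 and fA >= 1, "
            f"got kB={t.kB}, fA={t.fA}"
        )
    post_B = BetaParams(t.kB, t.fB + 1)
    post_A = BetaParams(t.kA + 1, t.fA)
    pr = prob_beta_greater(post_B, post_A)
    p = fisher_one_sided_p(t, "B_greater")
    return pr, p, abs(pr + p - 1.0)
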