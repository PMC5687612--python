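"""Simon two-stage designs: exact outcome probabilities and exhaustive search.

A Simon two-stage design for a single arm is the tuple ``(n1, r1, n, r)``:
enroll ``n1`` patients, stop for futility if at most ``r1`` respond, otherwise
enroll ``n2 = n - n1`` more and declare the treatment ineffective if the total
number of responders is at most ``r``.  An arm whose total responder count
exceeds ``r`` "passes" the second stage.

Everything downstream (winner rules, operating characteristics) is built on
the exact per-arm probabilities computed here from binomial sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.stats import binom

__all__ = [
    "Hypothesis",
    "SimonDesign",
    "DesignCharacteristics",
    "DesignSearchError",
    "pass_probability",
    "stage1_fail_probability",
    "pass_total_pmf",
    "search_simon_design",
    "design_characteristics",
]

DesignKind = Literal["optimal", "minimax"]


class DesignSearchError(RuntimeError):
    """No feasible two-stage design exists within the search bound."""


@dataclass(frozen=True)
class Hypothesis:
    """Per-arm hypothesis driving the design search.

    Parameters
    ----------
    p0 : float
        Unacceptable (null) response rate in ``[0, 1)``.
    p1 : float
        Promising (alternative) response rate in ``(0, 1]``; must exceed ``p0``.
    alpha : float
        Maximum type I error (probability of passing under ``p0``).
    beta_err : float
        Maximum type II error (probability of failing under ``p1``).
    """

    p0: float
    p1: float
    alpha: float
    beta_err: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 < 1.0:
            raise ValueError(f"p0 must be in [0, 1), got {self.p0}")
        if not 0.0 < self.p1 <= 1.0:
            raise ValueError(f"p1 must be in (0, 1], got {self.p1}")
        if self.p1 <= self.p0:
            raise ValueError(f"p1 must exceed p0, got p0={self.p0}, p1={self.p1}")
        for name in ("alpha", "beta_err"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass(frozen=True)
class SimonDesign:
    """A two-stage futility design ``(n1, r1, n2, n, r)``.

    ``r1`` and ``r`` are "stop" bounds: the arm stops at stage 1 if responders
    are at most ``r1``, and is declared ineffective if total responders are at
    most ``r``.
    """

    n1: int
    r1: int
    n2: int
    n: int
    r: int
    kind: str = "optimal"

    def __post_init__(self) -> None:
        if not (0 <= self.r1 < self.n1):
            raise ValueError(f"need 0 <= r1 < n1, got r1={self.r1}, n1={self.n1}")
        if not (self.r1 <= self.r < self.n):
            raise ValueError(f"need r1 <= r < n, got r1={self.r1}, r={self.r}, n={self.n}")
        if self.n2 < 1:
            raise ValueError(f"need n2 >= 1, got {self.n2}")
        if self.n != self.n1 + self.n2:
            raise ValueError(f"n must equal n1 + n2, got {self.n} != {self.n1} + {self.n2}")


@dataclass(frozen=True)
class DesignCharacteristics:
    """Exact operating characteristics of a single-arm two-stage design."""

    attained_alpha: float  # P(pass | p0)
    attained_power: float  # P(pass | p1)
    pet0: float            # probability of early termination under p0
    en0: float             # expected sample size under p0


def _check_rate(p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"response rate must be in [0, 1], got {p}")


def pass_probability(design: SimonDesign, p: float) -> float:
    """Exact probability that the arm passes both stages at response rate ``p``.

    Passing requires stage-1 responders ``x1 > r1`` and total responders
    ``x1 + x2 > r``:

        P(pass) = sum_{x1=r1+1}^{n1} Bin(x1; n1, p) P(X2 > r - x1)

    with ``X2 ~ Bin(n2, p)``.
    """
    _check_rate(p)
    x1 = np.arange(design.r1 + 1, design.n1 + 1)
    return float(
        np.sum(binom.pmf(x1, design.n1, p) * binom.sf(design.r - x1, design.n2, p))
    )


def stage1_fail_probability(design: SimonDesign, p: float) -> float:
    """Probability of stopping at stage 1 (responders at most ``r1``)."""
    _check_rate(p)
    return float(binom.cdf(design.r1, design.n1, p))


def pass_total_pmf(design: SimonDesign, p: float) -> dict[int, float]:
    """Joint probability of passing with exactly ``k`` total responders.

    Returns a map ``k -> P(x1 > r1 and x1 + x2 = k)`` for
    ``k in {r+1, ..., n}``.  Its total mass equals
    :func:`pass_probability`.  This is the quantity the winner rule needs:
    when both arms pass, the posterior comparison depends only on the total
    responder counts.
    """
    _check_rate(p)
    out: dict[int, float] = {}
    for k in range(design.r + 1, design.n + 1):
        lo = max(design.r1 + 1, k - design.n2)
        hi = min(design.n1, k)
        if lo > hi:
            out[k] = 0.0
            continue
        x1 = np.arange(lo, hi + 1)
        out[k] = float(
            np.sum(
                binom.pmf(x1, design.n1, p) * binom.pmf(k - x1, design.n2, p)
            )
        )
    return out


def design_characteristics(design: SimonDesign, h: Hypothesis) -> DesignCharacteristics:
    """Exact attained errors, early-termination probability and E[N | p0]."""
    pet0 = stage1_fail_probability(design, h.p0)
    return DesignCharacteristics(
        attained_alpha=pass_probability(design, h.p0),
        attained_power=pass_probability(design, h.p1),
        pet0=pet0,
        en0=design.n1 + (1.0 - pet0) * design.n2,
    )


def search_simon_design(
    h: Hypothesis,
    kind: DesignKind = "optimal",
    n_max: int = 100,
) -> tuple[SimonDesign, DesignCharacteristics]:
    """Exhaustive search for the optimal or minimax two-stage design.

    The optimal design minimizes the expected sample size under ``p0`` among
    designs with attained type I error at most ``alpha`` and power at least
    ``1 - beta_err``; the minimax design minimizes the maximum sample size
    ``n`` first, then ``EN(p0)``.  Ties are broken deterministically by
    smallest ``n``, then ``n1``, then ``r1``.

    Raises
    ------
    DesignSearchError
        If no feasible design has total sample size at most ``n_max``.
    """
    if kind not in ("optimal", "minimax"):
        raise ValueError(f"kind must be 'optimal' or 'minimax', got {kind!r}")
    if n_max < 2:
        raise ValueError(f"n_max must be at least 2, got {n_max}")

    best_key: tuple | None = None
    best: tuple[SimonDesign, DesignCharacteristics] | None = None

    for n in range(2, n_max + 1):
        # minimax: once a feasible design exists at some n, no larger n can win
        if kind == "minimax" and best is not None and best[0].n < n:
            break
        for n1 in range(1, n):
            n2 = n - n1
            x_all = np.arange(0, n1 + 1)
            pmf0 = binom.pmf(x_all, n1, h.p0)
            pmf1 = binom.pmf(x_all, n1, h.p1)
            cdf0 = np.cumsum(pmf0)
            for r1 in range(0, n1):
                x1 = np.arange(r1 + 1, n1 + 1)
                pet0 = float(cdf0[r1])
                en0 = n1 + (1.0 - pet0) * n2
                # the smallest EN(p0) any candidate at (n1, r1, n) can attain;
                # prune in the optimal search
                if kind == "optimal" and best_key is not None and (en0, n, n1, r1) >= best_key:
                    continue
                for r in range(r1, n):
                    a = float(np.sum(pmf0[x1] * binom.sf(r - x1, n2, h.p0)))
                    if a > h.alpha:
                        continue
                    power = float(np.sum(pmf1[x1] * binom.sf(r - x1, n2, h.p1)))
                    if power < 1.0 - h.beta_err:
                        # power decreases as r grows; larger r cannot recover
                        break
                    key = (
                        (en0, n, n1, r1) if kind == "optimal" else (n, en0, n1, r1)
                    )
                    if best_key is None or key < best_key:
                        design = SimonDesign(n1=n1, r1=r1, n2=n2, n=n, r=r, kind=kind)
                        best_key = key
                        best = (
                            design,
                            DesignCharacteristics(
                                attained_alpha=a,
                                attained_power=power,
                                pet0=pet0,
                                en0=en0,
                            ),
                        )
                    # among feasible r at fixed (n1, r1, n), the smallest r has
                    # the largest alpha; increasing r only shrinks both errors,
                    # leaving EN(p0) unchanged, so the first feasible r wins
                    break
    if best is None:
        raise DesignSearchError(
            f"no feasible design with n <= {n_max} for p0={h.p0}, p1={h.p1}, "
            f"alpha={h.alpha}, beta={h.beta_err}: search bound exceeded"
        )
    return best
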