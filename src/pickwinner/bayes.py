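"""Beta priors, conjugate posterior updating, and the winner probability.

The winner rule compares the two arms through independent beta posteriors on
their response rates.  With a ``Beta(a, b)`` prior and ``k`` responders out of
``n`` enrolled, the posterior is ``Beta(a + k, b + n - k)``; the winner
probability is ``Pr(B > A) = P(X > Y)`` for the two independent posteriors.

Four prior families are supported:

* ``noninformative`` — ``Beta(c, c)`` in both arms (``c = 0`` Haldane,
  ``c = 0.5`` Jeffreys, ``c = 1`` uniform);
* ``unfavorable_B`` — ``Beta(c, 0)`` in arm A and ``Beta(0, c)`` in arm B,
  tilting the comparison against arm B (at ``c = 1`` the resulting
  ``Pr(B > A)`` is the complement of the one-sided Fisher exact p-value,
  Altham's identity);
* ``favorable_B`` — the mirror image, ``Beta(0, c)`` in A and ``Beta(c, 0)``
  in B;
* ``moments`` — a proper prior per arm matched to a hypothesized or observed
  response rate (mean) and a prior standard deviation.

Improper priors (a zero shape) are representable; properness is enforced on
the posterior at probability-computation time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.special import gammaln
from scipy.stats import beta as beta_dist

__all__ = [
    "BetaParams",
    "PriorSpec",
    "PosteriorPair",
    "ImproperPosteriorError",
    "make_priors",
    "prior_from_moments",
    "posterior_params",
    "prob_beta_greater",
    "prior_sensitivity",
]

PriorFamily = Literal["noninformative", "unfavorable_B", "favorable_B", "moments"]


class ImproperPosteriorError(ValueError):
    """A beta distribution with a non-positive shape where a proper one is required."""


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters of a beta distribution; zero shapes mark improper priors."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError(f"beta shapes must be nonnegative, got ({self.a}, {self.b})")

    @property
    def proper(self) -> bool:
        return self.a > 0 and self.b > 0

    @property
    def mean(self) -> float:
        if not self.proper:
            raise ImproperPosteriorError(f"Beta({self.a}, {self.b}) has no mean")
        return self.a / (self.a + self.b)


@dataclass(frozen=True)
class PriorSpec:
    """One of the four prior families.

    ``c`` scales families ``noninformative`` / ``unfavorable_B`` /
    ``favorable_B``; ``mean_A``, ``mean_B`` and ``sd`` define the
    moment-matched family (``sd`` applies to both arms).
    """

    family: PriorFamily
    c: float = 1.0
    mean_A: float | None = None
    mean_B: float | None = None
    sd: float = 0.1

    def __post_init__(self) -> None:
        if self.family not in ("noninformative", "unfavorable_B", "favorable_B", "moments"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.family == "moments":
            if self.mean_A is None or self.mean_B is None:
                raise ValueError("family 'moments' requires mean_A and mean_B")
        elif self.c < 0:
            raise ValueError(f"c must be nonnegative, got {self.c}")

    def label(self) -> str:
        if self.family == "moments":
            return f"moments(mean_A={self.mean_A}, mean_B={self.mean_B}, sd={self.sd})"
        return f"{self.family}(c={self.c})"


@dataclass(frozen=True)
class PosteriorPair:
    arm_A: BetaParams
    arm_B: BetaParams

    def __post_init__(self) -> None:
        for name, params in (("A", self.arm_A), ("B", self.arm_B)):
            if not params.proper:
                raise ImproperPosteriorError(
                    f"posterior for arm {name} is improper: "
                    f"Beta({params.a}, {params.b})"
                )


def make_priors(spec: PriorSpec) -> tuple[BetaParams, BetaParams]:
    """Prior parameters ``(arm_A, arm_B)`` for a :class:`PriorSpec`."""
    if spec.family == "noninformative":
        return BetaParams(spec.c, spec.c), BetaParams(spec.c, spec.c)
    if spec.family == "unfavorable_B":
        return BetaParams(spec.c, 0.0), BetaParams(0.0, spec.c)
    if spec.family == "favorable_B":
        return BetaParams(0.0, spec.c), BetaParams(spec.c, 0.0)
    # moments
    assert spec.mean_A is not None and spec.mean_B is not None
    return (
        prior_from_moments(spec.mean_A, spec.sd),
        prior_from_moments(spec.mean_B, spec.sd),
    )


def prior_from_moments(mean: float, sd: float) -> BetaParams:
    """Beta parameters with the given mean and standard deviation.

    Method-of-moments inversion: ``a = mean (mean(1-mean)/sd^2 - 1)`` and
    ``b = a (1-mean)/mean``.  Requires ``sd^2 < mean (1 - mean)``.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must be in (0, 1), got {mean}")
    var = sd * sd
    if not 0.0 < var < mean * (1.0 - mean):
        raise ValueError(
            f"sd^2 must be in (0, mean(1-mean)) = (0, {mean * (1 - mean):.4g}), got {var:.4g}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return BetaParams(mean * nu, (1.0 - mean) * nu)


def posterior_params(prior: BetaParams, k: int, n: int) -> BetaParams:
    """Conjugate update: ``Beta(a, b)`` prior with ``k``/``n`` responders.

    Raises :class:`ImproperPosteriorError` when the update does not yield a
    proper distribution (e.g. the Haldane prior with zero responders).
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    a, b = prior.a + k, prior.b + n - k
    if a <= 0 or b <= 0:
        raise ImproperPosteriorError(
            f"posterior Beta({a}, {b}) from prior Beta({prior.a}, {prior.b}) "
            f"with k={k}, n={n} is improper"
        )
    return BetaParams(a, b)


def _is_int(x: float, tol: float = 1e-9) -> bool:
    return abs(x - round(x)) < tol and round(x) >= 1


def _prob_greater_int(aX: int, bX: int, y: BetaParams) -> float:
    """P(X > Y) for X ~ Beta(aX, bX) with integer shapes, Y proper beta.

    Uses the beta-binomial tail identity ``1 - F_X(y) = P(Bin(m, y) <= aX-1)``
    with ``m = aX + bX - 1``, so

        P(X > Y) = sum_{j<aX} C(m, j) B(aY + j, bY + m - j) / B(aY, bY),

    evaluated in log space for stability at large counts.
    """
    m = aX + bX - 1
    j = np.arange(0, aX)
    log_terms = (
        gammaln(m + 1) - gammaln(j + 1) - gammaln(m - j + 1)
        + gammaln(y.a + j) + gammaln(y.b + m - j) - gammaln(y.a + y.b + m)
        - (gammaln(y.a) + gammaln(y.b) - gammaln(y.a + y.b))
    )
    return float(np.sum(np.exp(log_terms)))


def prob_beta_greater(
    params_B: BetaParams, params_A: BetaParams, tol: float = 1e-8
) -> float:
    """``P(X > Y)`` for independent ``X ~ Beta(params_B)``, ``Y ~ Beta(params_A)``.

    Integer shapes use an exact closed-form summation; otherwise the integral
    ``int f_X(x) F_Y(x) dx`` is evaluated by adaptive quadrature to ``tol``.
    Both distributions are continuous, so ties have measure zero and
    ``P(X > Y) = P(X >= Y)``.
    """
    for name, p in (("B", params_B), ("A", params_A)):
        if not p.proper:
            raise ImproperPosteriorError(
                f"arm {name} distribution Beta({p.a}, {p.b}) is improper"
            )
    if _is_int(params_B.a) and _is_int(params_B.b):
        return min(1.0, _prob_greater_int(round(params_B.a), round(params_B.b), params_A))
    if _is_int(params_A.a) and _is_int(params_A.b):
        return min(1.0, 1.0 - _prob_greater_int(round(params_A.a), round(params_A.b), params_B))
    fx = beta_dist(params_B.a, params_B.b)
    Fy = beta_dist(params_A.a, params_A.b)
    val, _ = quad(
        lambda x: fx.pdf(x) * Fy.cdf(x), 0.0, 1.0,
        epsabs=tol * 1e-2, epsrel=tol * 1e-2, limit=200,
    )
    return float(min(1.0, max(0.0, val)))


def prior_sensitivity(
    kA: int, nA: int, kB: int, nB: int, specs: Iterable[PriorSpec]
) -> pd.DataFrame:
    """``Pr(B > A)`` for the same data under each prior specification.

    Returns one row per spec with columns ``prior``, ``family``, ``c``,
    ``prob_B_greater`` and ``proper``.  Rows whose posterior is improper are
    flagged (``proper=False``, probability NaN) rather than dropped.
    """
    rows = []
    for spec in specs:
        prior_A, prior_B = make_priors(spec)
        try:
            post_A = posterior_params(prior_A, kA, nA)
            post_B = posterior_params(prior_B, kB, nB)
            prob = prob_beta_greater(post_B, post_A)
            proper = True
        except ImproperPosteriorError:
            prob, proper = float("nan"), False
        rows.append(
            {
                "prior": spec.label(),
                "family": spec.family,
                "c": spec.c if spec.family != "moments" else float("nan"),
                "prob_B_greater": prob,
                "proper": proper,
            }
        )
    return pd.DataFrame(rows)
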