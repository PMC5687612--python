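"""Priors, conjugate updates, and the winner probability Pr(B > A)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pickwinner import (
    BetaParams,
    ImproperPosteriorError,
    PriorSpec,
    make_priors,
    posterior_params,
    prior_from_moments,
    prior_sensitivity,
    prob_beta_greater,
)
from pickwinner.bayes import _prob_greater_int


class TestMakePriors:
    def test_uniform_pair(self):
        assert make_priors(PriorSpec("noninformative", c=1.0)) == (
            BetaParams(1, 1),
            BetaParams(1, 1),
        )

    def test_unfavorable_pair(self):
        a, b = make_priors(PriorSpec("unfavorable_B", c=1.0))
        assert (a, b) == (BetaParams(1, 0), BetaParams(0, 1))
        assert not a.proper and not b.proper

    def test_favorable_pair_mirrors_unfavorable(self):
        a, b = make_priors(PriorSpec("favorable_B", c=2.5))
        assert (a, b) == (BetaParams(0, 2.5), BetaParams(2.5, 0))

    def test_haldane_improper_until_update(self):
        a, b = make_priors(PriorSpec("noninformative", c=0.0))
        assert not a.proper
        # data with responders and non-responders makes the posterior proper
        assert posterior_params(a, 3, 10) == BetaParams(3, 7)
        with pytest.raises(ImproperPosteriorError):
            posterior_params(b, 0, 10)

    def test_moment_family(self):
        a, b = make_priors(PriorSpec("moments", mean_A=0.2, mean_B=0.4, sd=0.1))
        assert a.mean == pytest.approx(0.2)
        assert b.mean == pytest.approx(0.4)


class TestPriorFromMoments:
    def test_sd_point_one_at_forty_percent(self):
        params = prior_from_moments(0.4, 0.1)
        assert params.a == pytest.approx(9.2, abs=1e-10)
        assert params.b == pytest.approx(13.8, abs=1e-10)

    @pytest.mark.parametrize("mean,sd", [(0.2, 0.1), (0.4, 0.1), (0.73, 0.05)])
    def test_round_trip_moments(self, mean, sd):
        p = prior_from_moments(mean, sd)
        total = p.a + p.b
        assert p.a / total == pytest.approx(mean, abs=1e-10)
        var = p.a * p.b / (total**2 * (total + 1))
        assert var == pytest.approx(sd**2, abs=1e-10)

    def test_uniform_limit(self):
        p = prior_from_moments(0.5, math.sqrt(1 / 12) - 1e-9)
        assert p.a == pytest.approx(1.0, abs=1e-6)
        assert p.b == pytest.approx(1.0, abs=1e-6)

    def test_variance_bound_violation(self):
        with pytest.raises(ValueError):
            prior_from_moments(0.5, 0.6)


class TestPosteriorUpdate:
    @pytest.mark.parametrize(
        "k,n,expected",
        [(31, 38, BetaParams(32, 8)), (20, 40, BetaParams(21, 21))],
    )
    def test_uniform_prior_update(self, k, n, expected):
        assert posterior_params(BetaParams(1, 1), k, n) == expected

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            posterior_params(BetaParams(1, 1), 5, 4)

    @given(
        k=st.integers(0, 30),
        n=st.integers(30, 60),
        split=st.integers(0, 30),
    )
    @settings(max_examples=50, derandomize=True)
    def test_update_commutes_with_data_splitting(self, k, n, split):
        prior = BetaParams(1, 1)
        k1 = min(k, split)
        n1 = split
        once = posterior_params(prior, k, n)
        staged = posterior_params(
            posterior_params(prior, k1, n1), k - k1, n - n1
        )
        assert once == staged


class TestProbBetaGreater:
    def test_gonzalez_martin_posterior(self):
        # 31/38 vs 20/40 under uniform priors
        assert prob_beta_greater(BetaParams(32, 8), BetaParams(21, 21)) == pytest.approx(
            0.998, abs=5e-4
        )

    def test_dark_posterior(self):
        # 6/39 vs 2/41 under uniform priors
        assert prob_beta_greater(BetaParams(7, 34), BetaParams(3, 40)) == pytest.approx(
            0.93, abs=5e-3
        )

    def test_identical_params_symmetric(self):
        assert prob_beta_greater(BetaParams(21, 21), BetaParams(21, 21)) == pytest.approx(
            0.5, abs=1e-12
        )

    def test_closed_form_small_case(self):
        # P(X > Y), X~Beta(2,1), Y~Beta(1,1): int 2x * x dx = 2/3
        assert prob_beta_greater(BetaParams(2, 1), BetaParams(1, 1)) == pytest.approx(
            2 / 3, abs=1e-12
        )

    def test_integer_sum_matches_quadrature(self):
        from scipy.integrate import quad
        from scipy.stats import beta as beta_dist

        for aB, bB, aA, bA in [(32, 8, 21, 21), (7, 34, 3, 40), (5, 2, 2, 9)]:
            direct, _ = quad(
                lambda x: beta_dist.pdf(x, aB, bB) * beta_dist.cdf(x, aA, bA),
                0, 1, epsabs=1e-12,
            )
            assert _prob_greater_int(aB, bB, BetaParams(aA, bA)) == pytest.approx(
                direct, abs=1e-10
            )

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(7)
        pairs = [(32, 8, 21, 21), (9.2, 13.8, 4.2, 17.8), (2.5, 2.5, 3, 3)]
        for aB, bB, aA, bA in pairs:
            n = 1_000_000
            x = rng.beta(aB, bB, n)
            y = rng.beta(aA, bA, n)
            phat = (x > y).mean()
            exact = prob_beta_greater(BetaParams(aB, bB), BetaParams(aA, bA))
            se = math.sqrt(max(exact * (1 - exact), 1e-12) / n)
            assert abs(phat - exact) < 3 * se + 1e-6

    @given(
        aB=st.floats(0.5, 40), bB=st.floats(0.5, 40),
        aA=st.floats(0.5, 40), bA=st.floats(0.5, 40),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_exchange_symmetry(self, aB, bB, aA, bA):
        p = prob_beta_greater(BetaParams(aB, bB), BetaParams(aA, bA))
        q = prob_beta_greater(BetaParams(aA, bA), BetaParams(aB, bB))
        assert p + q == pytest.approx(1.0, abs=1e-7)

    def test_monotone_in_first_shape(self):
        base = BetaParams(20, 20)
        vals = [
            prob_beta_greater(BetaParams(a, 20), base) for a in range(10, 31, 2)
        ]
        assert all(b >= a - 1e-10 for a, b in zip(vals, vals[1:]))

    def test_improper_input_rejected(self):
        with pytest.raises(ImproperPosteriorError):
            prob_beta_greater(BetaParams(0, 1), BetaParams(1, 1))


class TestPriorSensitivity:
    def test_noninformative_spread_small(self):
        specs = [PriorSpec("noninformative", c=c) for c in (0.0, 0.5, 1.0)]
        table = prior_sensitivity(kA=8, nA=37, kB=15, nB=37, specs=specs)
        assert table["proper"].all()
        vals = table["prob_B_greater"].to_numpy()
        assert vals.max() - vals.min() < 0.02

    def test_unfavorable_decreases_favorable_increases_in_c(self):
        cs = [0.1, 1.0, 10.0]
        unf = prior_sensitivity(
            8, 37, 15, 37, [PriorSpec("unfavorable_B", c=c) for c in cs]
        )["prob_B_greater"].to_numpy()
        fav = prior_sensitivity(
            8, 37, 15, 37, [PriorSpec("favorable_B", c=c) for c in cs]
        )["prob_B_greater"].to_numpy()
        assert unf[0] > unf[1] > unf[2]
        assert fav[0] < fav[1] < fav[2]

    def test_improper_rows_flagged_not_dropped(self):
        specs = [
            PriorSpec("noninformative", c=1.0),
            PriorSpec("noninformative", c=0.0),  # Haldane, improper with kA=0
        ]
        table = prior_sensitivity(kA=0, nA=10, kB=5, nB=10, specs=specs)
        assert len(table) == 2
        assert table["proper"].tolist() == [True, False]
        assert np.isnan(table.loc[1, "prob_B_greater"])
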