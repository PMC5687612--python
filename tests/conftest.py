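import pytest

from pickwinner import DecisionRule, Hypothesis, PriorSpec, SimonDesign


@pytest.fixture(scope="session")
def lung_hypothesis() -> Hypothesis:
    """20% unacceptable vs 40% promising response rate, 10% error rates."""
    return Hypothesis(p0=0.2, p1=0.4, alpha=0.1, beta_err=0.1)


@pytest.fixture(scope="session")
def lung_design() -> SimonDesign:
    """The Simon optimal design for the 20%-vs-40% hypothesis: (17, 3, 37, 10)."""
    return SimonDesign(n1=17, r1=3, n2=20, n=37, r=10)


@pytest.fixture(scope="session")
def uniform_prior() -> PriorSpec:
    return PriorSpec("noninformative", c=1.0)


@pytest.fixture(scope="session")
def default_rule(uniform_prior) -> DecisionRule:
    """delta = 0.8 with uniform priors in both arms."""
    return DecisionRule(delta=0.8, prior=uniform_prior)
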