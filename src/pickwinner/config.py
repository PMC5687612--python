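"""Plain-text (YAML/JSON) trial configuration.

Schema (all design parameters are required; no silent defaults)::

    p0: 0.2          # unacceptable response rate (both arms unless arm_A/arm_B given)
    p1: 0.4          # promising response rate
    alpha: 0.1       # per-arm type I error bound
    beta: 0.1        # per-arm type II error bound
    kind: optimal    # optimal | minimax
    delta: 0.8       # winner threshold
    prior:
      family: noninformative   # noninformative | unfavorable_B | favorable_B | moments
      c: 1.0
      # family 'moments' instead takes mean_A, mean_B, sd
    arm_A: {}        # optional per-arm overrides of p0/p1/alpha/beta
    arm_B: {}
    scenarios:       # optional true-rate pairs for operating characteristics
      - [0.2, 0.4]

YAML is a superset of JSON, so a JSON file parses with the same loader.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .bayes import PriorSpec
from .simon import Hypothesis

__all__ = ["TrialPlanConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class TrialPlanConfig:
    """Fully-specified two-arm trial plan."""

    hypothesis_A: Hypothesis
    hypothesis_B: Hypothesis
    kind: str
    delta: float
    prior: PriorSpec
    scenarios: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("optimal", "minimax"):
            raise ValueError(f"kind must be 'optimal' or 'minimax', got {self.kind!r}")
        if not 0.5 <= self.delta < 1.0:
            raise ValueError(f"delta must be in [0.5, 1), got {self.delta}")
        for pA, pB in self.scenarios:
            for p in (pA, pB):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"scenario rate {p} outside [0, 1]")


_REQUIRED = ("p0", "p1", "alpha", "beta", "delta")


def _hypothesis(data: dict, overrides: dict) -> Hypothesis:
    merged = {**data, **overrides}
    return Hypothesis(
        p0=float(merged["p0"]),
        p1=float(merged["p1"]),
        alpha=float(merged["alpha"]),
        beta_err=float(merged["beta"]),
    )


def parse_config(data: dict) -> TrialPlanConfig:
    missing = [k for k in _REQUIRED if k not in data]
    if missing:
        raise ValueError(f"config missing required keys: {', '.join(missing)}")
    prior_data = dict(data.get("prior", {"family": "noninformative", "c": 1.0}))
    family = prior_data.pop("family", "noninformative")
    prior = PriorSpec(family=family, **{k: float(v) for k, v in prior_data.items()})
    scenarios = tuple(
        (float(pA), float(pB)) for pA, pB in data.get("scenarios", []) or []
    )
    return TrialPlanConfig(
        hypothesis_A=_hypothesis(data, data.get("arm_A", {}) or {}),
        hypothesis_B=_hypothesis(data, data.get("arm_B", {}) or {}),
        kind=str(data.get("kind", "optimal")),
        delta=float(data["delta"]),
        prior=prior,
        scenarios=scenarios,
    )


def load_config(path: str | Path) -> TrialPlanConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} did not parse to a mapping")
    return parse_config(data)


def dump_config(cfg: TrialPlanConfig) -> str:
    """Serialize a config so that it re-parses to an equivalent object."""
    hA, hB = cfg.hypothesis_A, cfg.hypothesis_B
    data: dict = {
        "p0": hA.p0,
        "p1": hA.p1,
        "alpha": hA.alpha,
        "beta": hA.beta_err,
        "kind": cfg.kind,
        "delta": cfg.delta,
        "prior": {
            k: v
            for k, v in dataclasses.asdict(cfg.prior).items()
            if v is not None
        },
        "scenarios": [list(s) for s in cfg.scenarios],
    }
    if hB != hA:
        data["arm_B"] = {
            "p0": hB.p0, "p1": hB.p1, "alpha": hB.alpha, "beta": hB.beta_err,
        }
    return yaml.safe_dump(data, sort_keys=False)
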