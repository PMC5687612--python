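"""Seeded Monte Carlo simulation of complete two-arm pick-the-winner trials.

The simulator cross-validates the exact enumeration and covers settings the
enumeration does not (e.g. diagnostics on sample-size distributions).

Streaming contract: replicates are processed in fixed blocks of 10,000; block
``j`` draws from ``Generator(PCG64(SeedSequence((seed, j))))``.  The block
size is an implementation constant, so results depend only on ``(seed,
reps)`` and are unaffected by how a caller chunks or streams replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .oc import STATUS_LABELS, _winner_prob_table
from .rules import DecisionRule, TrialResult, classify_arm, pick_winner
from .simon import SimonDesign

__all__ = ["SimulationConfig", "SimulationSummary", "simulate_trial", "simulate_oc"]

_BLOCK = 10_000


@dataclass(frozen=True)
class SimulationConfig:
    design_A: SimonDesign
    design_B: SimonDesign
    pA: float
    pB: float
    rule: DecisionRule
    reps: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError(f"reps must be at least 1, got {self.reps}")
        for name in ("pA", "pB"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.rule.comparator != "bayes":
            raise ValueError("simulation currently supports the Bayes comparator only")


@dataclass(frozen=True)
class SimulationSummary:
    """Replicate counts and proportions with Monte Carlo standard errors."""

    reps: int
    cell_counts: pd.DataFrame      # 3x3 joint status counts (A rows, B columns)
    cell_props: pd.DataFrame
    winner_counts: dict[str, int]  # "A" / "B" / "none"
    winner_props: dict[str, float]
    winner_se: dict[str, float]
    mean_total_sample_size: float

    def prop_se(self, p: float) -> float:
        return float(np.sqrt(p * (1.0 - p) / self.reps))


def _simulate_arm(
    design: SimonDesign, p: float, rng: np.random.Generator, size: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized draw of (x1, total k, pass flag) for ``size`` replicates."""
    x1 = rng.binomial(design.n1, p, size=size)
    cont = x1 > design.r1
    x2 = np.zeros(size, dtype=np.int64)
    # stage-2 draws only for continuing replicates; draw order inside a block
    # is fixed by this masked layout
    x2[cont] = rng.binomial(design.n2, p, size=int(cont.sum()))
    k = x1 + x2
    passed = cont & (k > design.r)
    return x1, k, passed


def simulate_trial(cfg: SimulationConfig, rng: np.random.Generator) -> TrialResult:
    """One complete trial: stage-wise binomial draws, then the winner rule."""
    x1A = int(rng.binomial(cfg.design_A.n1, cfg.pA))
    kA = x1A
    if x1A > cfg.design_A.r1:
        kA += int(rng.binomial(cfg.design_A.n2, cfg.pA))
    x1B = int(rng.binomial(cfg.design_B.n1, cfg.pB))
    kB = x1B
    if x1B > cfg.design_B.r1:
        kB += int(rng.binomial(cfg.design_B.n2, cfg.pB))
    outcome_A = classify_arm(x1A, kA, cfg.design_A)
    outcome_B = classify_arm(x1B, kB, cfg.design_B)
    return pick_winner(outcome_A, outcome_B, cfg.rule)


def simulate_oc(cfg: SimulationConfig) -> SimulationSummary:
    """Aggregate operating characteristics over ``cfg.reps`` replicates."""
    table = _winner_prob_table(cfg.design_A, cfg.design_B, cfg.rule.prior)
    # dense lookup of Pr(B>A) indexed by (kA, kB); NaN marks non-pass counts
    pr = np.full((cfg.design_A.n + 1, cfg.design_B.n + 1), np.nan)
    for (kA, kB), v in table.items():
        pr[kA, kB] = v

    cells = np.zeros((3, 3), dtype=np.int64)
    winners = {"A": 0, "B": 0, "none": 0}
    total_n = 0

    done = 0
    block_idx = 0
    while done < cfg.reps:
        size = min(_BLOCK, cfg.reps - done)
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence((cfg.seed, block_idx)))
        )
        x1A, kA, passA = _simulate_arm(cfg.design_A, cfg.pA, rng, size)
        x1B, kB, passB = _simulate_arm(cfg.design_B, cfg.pB, rng, size)

        statA = np.where(x1A <= cfg.design_A.r1, 0, np.where(passA, 2, 1))
        statB = np.where(x1B <= cfg.design_B.r1, 0, np.where(passB, 2, 1))
        np.add.at(cells, (statA, statB), 1)

        nA = np.where(statA == 0, cfg.design_A.n1, cfg.design_A.n)
        nB = np.where(statB == 0, cfg.design_B.n1, cfg.design_B.n)
        total_n += int(nA.sum() + nB.sum())

        both = passA & passB
        only_B = passB & ~passA
        only_A = passA & ~passB
        winners["B"] += int(only_B.sum())
        winners["A"] += int(only_A.sum())
        if both.any():
            prob = pr[kA[both], kB[both]]
            hi, lo = cfg.rule.delta, 1.0 - cfg.rule.delta
            b_win = (prob > hi) & (np.abs(prob - hi) > 1e-9)
            a_win = (prob < lo) & (np.abs(prob - lo) > 1e-9)
            edge = ~b_win & ~a_win & (
                (np.abs(prob - hi) <= 1e-9) | (np.abs(prob - lo) <= 1e-9)
            )
            # threshold-boundary replicates are decided by a fair coin, the
            # sampling analogue of the enumeration's even split
            if edge.any():
                flip = rng.random(int(edge.sum())) < 0.5
                b_win[np.flatnonzero(edge)[flip]] = True
                a_win[np.flatnonzero(edge)[~flip]] = True
            winners["B"] += int(b_win.sum())
            winners["A"] += int(a_win.sum())
            winners["none"] += int(both.sum() - b_win.sum() - a_win.sum())
        winners["none"] += int(size - both.sum() - only_A.sum() - only_B.sum())

        done += size
        block_idx += 1

    idx = pd.Index(STATUS_LABELS, name="arm_A")
    cols = pd.Index(STATUS_LABELS, name="arm_B")
    counts = pd.DataFrame(cells, index=idx, columns=cols)
    props = counts / cfg.reps
    wprops = {k: v / cfg.reps for k, v in winners.items()}
    wse = {k: float(np.sqrt(p * (1.0 - p) / cfg.reps)) for k, p in wprops.items()}
    return SimulationSummary(
        reps=cfg.reps,
        cell_counts=counts,
        cell_props=props,
        winner_counts=winners,
        winner_props=wprops,
        winner_se=wse,
        mean_total_sample_size=total_n / cfg.reps,
    )
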