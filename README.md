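# pickwinner

Design and analysis of **Bayesian pick-the-winner** randomized phase II
clinical trials.

Multi-arm phase II oncology trials screen experimental regimens and advance
the most promising one ("the winner") to phase III. Classical selection
designs pick the arm with the highest observed response rate, without a
formal comparison, which inflates false positives. This package implements a
two-arm design that combines three components:

1. **Per-arm Simon two-stage futility designs.** Each arm enrolls `n1`
   patients; if at most `r1` respond the arm stops. Otherwise it enrolls
   `n2` more (total `n`) and is declared ineffective if total responders are
   at most `r`. An arm with more than `r` responders is *competitive*.
2. **A beta-posterior winner rule.** With a `Beta(a, b)` prior on the
   response rate and `k` responders out of `n`, the posterior is
   `Beta(a + k, b + n − k)`. When both arms are competitive, the winner
   probability is

   ```
   Pr(B > A) = P(X > Y),   X ~ Beta(a + k_B, b + n_B − k_B),
                           Y ~ Beta(a + k_A, b + n_A − k_A)
   ```

   Arm B wins if `Pr(B > A) > δ`; arm A wins if `Pr(B > A) < 1 − δ`;
   otherwise no clear winner is declared. If only one arm is competitive it
   wins outright; if neither is, there is no winner.
3. **Exact operating characteristics.** The two arms are independent, so the
   joint distribution over the nine status cells (fail stage 1 / fail stage 2
   / pass, per arm) and over all both-pass responder-count pairs is
   enumerated exactly — power, type I error and the full outcome matrix
   involve no simulation (a seeded Monte Carlo simulator is included as a
   cross-check). One-sided Fisher exact test comparators and single-stage
   randomized-trial benchmarks are built in, along with the classical
   identity that the Bayesian rule under the maximally unfavorable improper
   prior pair `Beta(1,0)/Beta(0,1)` reproduces the one-sided Fisher test.

Intended users: trial statisticians designing randomized phase II selection
trials, and anyone reproducing or extending the operating characteristics of
such designs.

## Worked example

Find the per-arm design for an unacceptable 20% versus a promising 40%
response rate with 10% type I and II error rates:

```text
$ pickwinner design --p0 0.2 --p1 0.4 --alpha 0.1 --beta 0.1
Simon optimal two-stage design for p0=0.2, p1=0.4 (alpha<=0.1, power>=0.9)
  stage 1: enroll 17, stop if responders <= 3
  stage 2: enroll 20 more (total 37), ineffective if total <= 10
  attained alpha 0.0948, power 0.9033, PET(p0) 0.5489, EN(p0) 26.02
```

Each arm enrolls 17 patients, stops early on 3 or fewer responders, and
needs more than 10 of 37 total responders to be competitive; the attained
error rates and the expected sample size under the null (26 patients,
because 55% of null arms stop early) characterize the design.

Apply the winner rule to a completed trial — 31/38 responders in arm B
versus 20/40 in arm A, uniform priors:

```text
$ pickwinner winner --ka 20 --na 40 --kb 31 --nb 38 --delta 0.8
Posterior A: Beta(21, 21); posterior B: Beta(32, 8)
Pr(B > A) = 0.998
At delta = 0.8: arm B is the winner
```

There is a 99.8% posterior probability that B's true response rate is
higher, far above the 0.8 threshold.

Exact operating characteristics when the true rates are 40% (B) vs 20% (A):

```text
$ pickwinner oc --config trial.yaml --pa 0.2 --pb 0.4
True rates: arm B 0.4 vs arm A 0.2 (bayes comparator)
arm_B        fail_stage1  fail_stage2    pass
arm_A
fail_stage1       0.0255       0.0276  0.4958
fail_stage2       0.0165       0.0179  0.3219
pass              0.0044       0.0048  0.0856
both competitive: 0.0856  local B win: 0.0402
overall: B 0.8579  A 0.0095  none 0.1326
```

Reading the `pass` column: with probability 0.50 arm A stops early while B
passes, with probability 0.32 A fails at stage 2 while B passes — in both
cases B wins outright — and with probability 0.086 both arms are
competitive, of which 0.040 ends with `Pr(B > A) > 0.8`. The overall power
to declare B the winner is 86%.

Other subcommands: `decide` (classify observed stage-wise counts and apply
the rule), `crt` (single-stage randomized benchmark), `fisher` (one-sided
exact test), `simulate` (seeded Monte Carlo cross-check), and `report`,
which renders a protocol-ready statistical plan from a YAML/JSON config (see
`pickwinner.config` for the schema). Everything is also available as a
library (`import pickwinner`).

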