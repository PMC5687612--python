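# Methods

## The design

Patients are randomized between arms A and B; each arm runs its own Simon
two-stage futility design `(n1, r1, n, r)`. Stage-1 responders `x1 ≤ r1`
stop the arm after `n1` patients; otherwise the arm completes `n = n1 + n2`
patients and is *competitive* iff total responders `k > r`. The trial-level
decision is:

| arm A \ arm B | fails | competitive |
|---|---|---|
| **fails** | no winner | B wins |
| **competitive** | A wins | winner by `Pr(B > A)` vs `δ` |

`Pr(B > A)` is the probability that B's true response rate exceeds A's under
independent beta posteriors. With prior `Beta(a, b)` and data `k/n` the
posterior is `Beta(a + k, b + n − k)` (the stopping rule enters the
likelihood only through a constant factor, so conjugate updating applies to
the realized counts). B is declared winner if `Pr(B > A) > δ`, A if
`Pr(B > A) < 1 − δ`, and no clear winner otherwise. The indeterminate band
is a deliberate reading of the decision table, which is silent on
intermediate probabilities; it is conservative and matches power definitions
that count only `Pr > δ` as a B win.

## Parameters that matter

- `p0`, `p1` — unacceptable and promising response rates (defaults in the
  examples: 0.20 / 0.40, typical of immunotherapy response screening).
- `alpha`, `beta` — per-arm error bounds for the design search (0.10 each in
  the examples). The search treats them as constraints on the attained
  (exact) error rates, the standard convention.
- `δ` — winner threshold on `Pr(B > A)`, in `[0.5, 1)`. `δ = 0.5` makes the
  winner a coin flip on tied evidence; `δ = 0.8` (default) trades a 2-fold
  local power reduction for an order-of-magnitude drop in local type I error
  and corresponds to roughly a 10-point observed response-rate difference on
  ~37-patient arms.
- Prior family — `noninformative` `Beta(c, c)` (`c` = 0 Haldane, 0.5
  Jeffreys, 1 uniform; the three differ in `Pr(B > A)` by < 0.02 at trial
  scale), improper tilted pairs `unfavorable_B` / `favorable_B`
  (`Beta(c,0)/Beta(0,c)` and its mirror), and `moments` (per-arm mean with a
  prior SD, default 0.1, inverted by method of moments). The uniform prior
  is the default for winner determination.

## Numerical choices

- **Design search.** Exhaustive over `(n, n1, r1, r)` with `n ≤ n_max`
  (default 100), pruned by two monotonicity facts: at fixed `(n1, r1, n)`
  both attained error rates fall as `r` grows while `EN(p0)` is unchanged,
  so only the smallest feasible `r` matters; and a candidate whose `EN(p0)`
  already exceeds the incumbent cannot win the optimal criterion. Ties break
  deterministically (smallest `n`, then `n1`, then `r1`). The search bound
  and tie-break are this package's choices; published designs at these
  sample sizes are well inside the bound, and an infeasible search raises an
  explicit error rather than returning a best effort.
- **`P(X > Y)` for beta pairs.** When X has integer shapes, the exact
  summation `P(X > Y) = Σ_{j<a_X} C(m, j) B(a_Y + j, b_Y + m − j)/B(a_Y,
  b_Y)` with `m = a_X + b_X − 1` (the beta–binomial tail identity),
  evaluated in log space; symmetrically via `1 − P(Y > X)` if only Y has
  integer shapes; otherwise adaptive quadrature of `∫ f_X F_Y` to an
  absolute tolerance of 1e−10 (default API tolerance 1e−8). Ties between
  continuous posteriors have measure zero, so `P(X > Y) = P(X ≥ Y)`.
- **Improper priors** are representable (`Beta(c, 0)` etc.); properness is
  enforced on the *posterior* when a probability is requested, with the
  offending arm named in the error. This is required because the tilted
  prior families are only posterior-proper.
- **Exact operating characteristics.** Arms are independent, so the 3×3
  status matrix is an outer product of per-arm probabilities from binomial
  sums, and the both-pass cell decomposes over the ≤ 27×27 passing
  total-count pairs, each weighted by its joint probability and classified
  by the winner rule. No sampling is involved; the matrix sums to 1 to
  1e−12.
- **Threshold-boundary mass.** Probability mass with `Pr(B > A)` exactly at
  the threshold (within 1e−9) is split evenly between the arms in the
  enumeration. With uniform priors and equal arm sizes this happens only for
  tied counts at `δ = 0.5`, where the rule is a coin flip on no evidence; the
  convention makes the local misclassification at `δ = 0.5` exactly half the
  both-pass probability and is inert for any `δ > 0.5`. A single observed
  trial, by contrast, reports "no clear winner" on a knife edge
  (`pick_winner` guards the comparison at 1e−9) — a report for one trial
  should not flip a coin silently.
- **Fisher comparator and CRT benchmark.** The one-sided p-value is the
  hypergeometric tail conditioning on both margins, observed table included
  (the standard convention); rejection is strict (`p < α`). The single-stage
  benchmark enumerates all binomial count pairs; its attained size falls
  below the nominal level because of the discreteness of the exact test, and
  whether the historical 62%-power figure used strict or non-strict
  rejection at the 9% level is not documented — strict rejection is used
  here and reproduces it.
- **Simulator streaming contract.** Replicates are processed in fixed
  blocks of 10,000; block `j` draws from
  `Generator(PCG64(SeedSequence((seed, j))))` with a fixed draw layout
  (stage-1 vector, then stage-2 vector for continuing replicates), so
  results depend only on `(seed, reps)`, not on how a caller batches work.
  Boundary replicates at `δ = 0.5` are resolved by a fair coin from the same
  stream, mirroring the enumeration's even split.

## What the checks do and do not show

The test suite validates the machinery against independent routes:
brute-force double summations for the two-stage probabilities, a 1e6-draw
Monte Carlo oracle for `P(X > Y)`, full margin-enumeration for the Fisher
tail, an exhaustive small-table sweep for the Fisher/unfavorable-prior
identity (discrepancy < 1e−10), and 1e5-replicate simulations agreeing with
the enumeration within 3 Monte Carlo standard errors on every tabulated
scenario. Reference figures quoted from published simulation studies are
matched at their printed rounding; where this package's exact values differ
from simulation-rounded figures in the second decimal of a percent (e.g.
both-pass under the null 0.898% exact vs 0.93% simulated), the exact value
is reported.

Two caveats. First, the approximate reading of `Pr(B > A)` as a
response-rate difference (0.80 ≈ 10 points) holds on the count pairs a trial
at the stated rates can realistically produce; over *all* algebraically
possible both-pass pairs the within-difference spread of `Pr(B > A)` reaches
0.20 at extreme counts that carry essentially no probability. Second, all
operating characteristics condition on the binomial model with a constant
per-arm response rate and independent arms — randomization motivates the
comparability assumption but nothing here models covariates, accrual timing
or dropout.

## Scope and limitations

Two arms only (the posterior comparison generalizes to more arms, but the
decision calculus implemented is the two-arm table); futility-only stopping
(no efficacy interims, no interim winner declarations); equal randomization;
binary endpoints. Arms may use different design parameters, although equal
designs keep `Pr(B > A)` symmetric in the observed counts. Problem sizes
throughout (37–41 patients per arm, ≤ 27×27 enumeration cells, 1e5–1e6
replicate cross-checks) are those of the trials this design targets, and all
computations complete in seconds.
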