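# Methods

## Probability model and inference

Each of the four decision-tree probabilities is modelled independently as a
Bernoulli rate p with a Beta(α, β) prior, where α and β are pseudo event /
non-event counts taken from published cohorts, and a Binomial(n, k)
observation from a prospective cohort treated without fosaprepitant. The
posterior is conjugate, Beta(α + k, β + n − k), and
`inference.conjugate_posterior` returns it in closed form. The Markov chain
Monte Carlo sampler exists to mirror the simulation-based workflow the
analysis is built around and to supply draws for propagating uncertainty;
its correctness is pinned to the conjugate oracle (chain mean within three
Monte-Carlo standard errors of the exact mean), not to any particular
reference sampler.

`inference.mh_sample` is a Gaussian random-walk Metropolis-Hastings sampler
on θ = logit(p). The transform keeps every draw strictly inside (0, 1); the
Jacobian p(1 − p) is absorbed into the target, which becomes
π(θ) ∝ σ(θ)^A σ(−θ)^B for posterior shapes (A, B), evaluated with
`logaddexp` for stability. Defaults are 12,500 iterations with 2,500
burn-in (10,000 retained draws). During burn-in the proposal standard
deviation is rescaled every 50 iterations by exp(observed − 0.44), clamped
to [10⁻³, 50], targeting the classical ~44% acceptance optimum for
one-dimensional random walks; it is frozen afterwards so the retained chain
is time-homogeneous. The chain starts at the logit of the conjugate
posterior mean, which makes burn-in generous rather than necessary. A
post-burn-in acceptance rate of exactly 0 or 1 raises
`DegenerateChainError`.

Credible intervals are equal-tailed percentile intervals of the retained
draws (not HPD), matching the symmetric intervals of the reference results;
the median is the sample median of the draws. Diagnostics
(`inference.diagnose`) compute the sample autocorrelation function and the
truncated autocorrelation-sum effective sample size,
ESS = n / (1 + 2·Σρ_k), summing lags until the first negative
autocorrelation; efficiency = ESS / n can exceed 1 slightly by estimator
noise. An all-equal chain is reported as perfectly correlated (ρ ≡ 1) by
convention. The test suite cross-checks this estimator against arviz's
rank-based ESS.

Seeding: one master seed feeds a `numpy` generator that hands each of the
four probabilities a sub-seed below 2³¹, so the chains are mutually
independent but jointly reproducible; a fixed seed reproduces every chain,
table and report byte-for-byte.

## Dose expectations

Low-risk patients escalate onto fosaprepitant from the cycle after their
first grade ≥3 episode and stay on it. With a constant per-phase toxicity
rate P₂ and two evaluation phases (after cycles 1 and 2), a low-risk
patient is on prophylaxis at cycle 2 with probability P₂ and at cycle 3
with probability 1 − (1 − P₂)². This cumulative-complement rule is a
reconstruction — the source never writes the low-risk formula — chosen
because it reproduces the published per-patient genotyping drug cost to
within $0.10, where the additive alternative (2·P₂) misses by ~$0.60.

Two dose-accounting conventions are first-class because the published
numbers require both. *Intent-to-treat* (all three planned cycles costed
regardless of dropout) underlies the per-patient figures: standard cost
3 × $81.08 = $243.24, genotyping ≈ $156, and the break-even thresholds.
*Dropout-adjusted* (cycle weights 1, P₃, P₃·P₄) underlies the annual
300-patient totals. Every report row is labelled with its convention. The
components are treated as independent — toxicity does not alter
continuation — as the arithmetic of the reference totals implies. A small
($0.16) internal inconsistency exists in the reference figures between
$243.24 and $243.40 for the standard per-patient cost; this package uses
3 × unit price throughout.

## Cost engine

Per-test cost for a batch of n samples: staff time (3 h 56 m extraction,
2 h 20 m PCR, 20 m reporting, at $1,585.65 per 160-hour month) divided by
n; DNA-extraction reagent constant per sample; PCR reagent and material
priced per reaction and scaled by (n + 4)/n for the four controls every run
carries. Per-reaction prices are the published single-test lines divided by
the 5 reactions of a one-sample run ($8.56/5, $1.07/5); the 10%
reagent-loss uplift is taken as already folded into those unit prices. The
stage durations are kept unrounded (the rounded 3.93/2.33/0.33 h versions
do not reproduce the single-sample manpower cells). All arithmetic is
unrounded; only the per-test total is rounded to cents (last), and that
cents value is the price used downstream, as a billed price would be.
Batch sizes above 6 (the weekly throughput the model was calibrated for)
are allowed with a warning.

Amortization is machine_cost × rate (defaults $36,364.86 × 20% =
$7,272.97/year). The published initial investment ($39,379.97) exceeds the
machine price with no printed breakdown; it is carried as an opaque
reporting constant and takes no part in any computation.

Break-even: N\* = max(1, ⌈amortization / m⌉) with per-patient margin
m = standard drug cost − genotyping drug cost − per-test cost,
intent-to-treat; m ≤ 0 raises `NeverBreaksEvenError`. Uncertainty
propagation pairs the four chains' draws by index, evaluates drug cost,
reduction percent, threshold and per-patient overall difference per draw,
and summarises each with an equal-tailed interval; threshold quantiles use
the inverted-CDF (order-statistic) method since the quantity is
integer-valued, and draws that never break even enter as +∞ in the upper
tail. Point estimates are the quantities evaluated at the posterior-mean
probabilities — the reference's own convention — so a point sits inside
its interval only up to Monte-Carlo noise. Note that at the *exact*
conjugate posterior means the two-sample threshold is 154; the published
155 corresponds to the three-decimal rounded means, and chain means land
on either value depending on the seed.

## Synthetic cohorts

`cohort.generate_cohort` draws independent per-patient Bernoulli outcomes:
genotype ~ P₁, grade ≥3 CINV per evaluation phase ~ P₂ (independent across
phases given the patient), cycle-2 receipt ~ P₃ and cycle-3 receipt ~ P₄
conditional on cycle 2. Default true probabilities in tests are the
posterior means (0.587, 0.139, 0.947, 0.748). Aggregation reproduces the
observed-data denominator conventions: the toxicity denominator is the
evaluable subset (a configurable `evaluable_fraction`, default 1.0 —
the reference's toxicity denominator of 43 out of 88 patients is not
explained, so the generator permits a subset without guessing a mechanism)
and the cycle-3 denominator is the number of cycle-2 receivers. The
generator emulates exactly the independence structure the analysis
assumes; it does not model per-cycle toxicity heterogeneity, sub-grade-3
CINV, Hardy-Weinberg genotype structure or covariates, so passing
calibration tests demonstrates internal consistency of the pipeline, not
robustness to real-data violations of those assumptions.

`cohort.parameter_recovery` closes the loop (generate → aggregate → infer →
summarise) and reports posterior-mean bias and empirical interval coverage.
Its default sampler is shortened to 3,000 iterations / 500 burn-in — a
one-dimensional chain needs far less than the headline settings for stable
95% intervals — so a 200-replicate, 500-patient calibration run finishes in
seconds. With flat Beta(1, 1) priors its 95% intervals cover the truth
within 95% ± 4 points per probability.

## Numerical and design choices

- Probabilities are validated strictly inside (0, 1) for economic
  evaluation; boundary behaviour is exercised in tests via limits
  (e.g. 1 − 10⁻¹²). Degenerate observations (0 of n, n of n, even 0 of 0)
  are legal; the proper prior keeps the posterior proper.
- Displayed tables round USD to cents and probabilities to three decimals;
  machine-readable outputs keep full precision.
- The published per-test table carries one cell-rounding inconsistency
  (n = 4 total $21.67 vs the unrounded-sum $21.66); comparisons use a
  ±$0.01 tolerance per cell.
- The propagated credible intervals are reproduced only approximately
  (each bound within a few percent): the reference's chain realizations
  are unknown, and its intervals are slightly wider than four independent
  conjugate-posterior chains yield.
- Config is a single YAML file merged over packaged defaults that
  reproduce the published inputs exactly; schema errors name the field.
  The manifest records seed, config hash and library versions, and omits
  timestamps so identical runs are byte-identical.
- No currency conversion, discounting, QALY modelling, or costing of the
  drugs common to both branches (dexamethasone, ondansetron, cisplatin
  cancel out of the comparison).
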