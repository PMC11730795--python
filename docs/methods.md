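# Methods

## Model and scope

The package evaluates binary diagnostic classification derived from
continuous (or already 0/1-coded) measurements. A subject is classified
positive when its value lies on the disease side of a cutoff — `value ≥
cutoff` by default, with a per-variable `le` flag for assays where low
values indicate disease. Truth and every candidate test are dichotomized
independently, and each test is cross-classified against the truth in a 2×2
table. All sixteen accuracy measures are deterministic functions of the four
cells (a, b, c, d); the statistical model underlying every interval is that
each relevant proportion is a binomial sample from its margin.

Missing handling is per-test listwise deletion: a row is dropped from one
test's table when the truth value or *that* test's value is missing, so
different tests in one report may use different n. The `excluded` count on
each table records the rows dropped this way. A row-filter condition
(restricted to `column op number` clauses joined by `and`) and an
equality-based domain (subgroup) filter are applied before counting.

## Confidence intervals

* **Proportion measures** (sensitivity, specificity, PPV, NPV, FPR, FNR,
  FOR, FDR, accuracy, prevalence): one of three binomial constructions,
  chosen by `varmethod`:
  * `normal` (default) — Wald, p̂ ± z₁₋α/₂·√(p̂(1−p̂)/n). Bounds are *not*
    clipped to [0, 1] by default (`clip_wald` turns clipping on): overshoot
    and the zero-width degeneracy at p̂ ∈ {0, 1} are documented properties
    of the method, and hiding them silently would misrepresent it.
  * `wilson` — the score interval; asymmetric, always inside [0, 1],
    preferable at small n. Bounds are clamped against floating-point spill
    of order 1e−17 at the endpoints.
  * `exact` — Clopper–Pearson from beta quantiles, with the closed forms
    (0, 1−(α/2)^(1/n)) at x = 0 and ((α/2)^(1/n), 1) at x = n. Conservative:
    coverage is at least nominal for every (p, n), which the test suite
    verifies by summing binomial probabilities over covering outcomes.
* **Ratio measures**: log-method intervals exp(ln R ± z·se) with
  se(ln LR+) = √(1/a − 1/m₁ + 1/b − 1/m₂), the analogous expression for
  LR−, and the Woolf se(ln DOR) = √(1/a + 1/b + 1/c + 1/d).
* **Kappa**: κ ± z·√(p₀(1−p₀)/(n(1−pₑ)²)), truncated to [−1, 1].
* **Youden's J**: J ± z·√(var(sens) + var(spec)) with Wald variances — the
  two proportions come from independent margins, so their variances add.
* **F-score**: the selected binomial method applied to x = 2a successes in
  n = 2a+b+c trials. The F-score is not literally a binomial proportion;
  this construction (like the Youden one) is a pragmatic choice the package
  makes where no standard closed form exists, and both reproduce the
  published reference values at 1-decimal rounding. They should be treated
  as approximate.

z is always the standard normal quantile at 1−α/2, never a hard-coded 1.96,
so any α ∈ (0, 1) is supported.

### Zero cells

Ratio measures on tables with an empty cell use the Haldane–Anscombe
correction: 0.5 is added to *all four* cells for that measure (and its
interval) only, keeping multi-test reports total. The same trigger — any
empty cell — is used for the point estimate and its interval so the pair
stays mutually consistent. Setting `zero_cell_correction=False` instead
reports a measure undefined when its own denominator vanishes (b = 0 for
LR+, d = 0 for LR−, bc = 0 for DOR) and an interval undefined when any cell
in its standard error is empty. Undefined quantities propagate to the report
as the configured missing label, never as 0: "not estimable" and "estimated
as zero" are different findings.

## ROC and PR curves

The threshold sweep visits every distinct observed score once (ties collapse
to a single threshold), calling a subject positive at threshold t when score
≥ t. The ROC curve carries (0,0) and (1,1) anchors; its trapezoidal area
equals the Mann–Whitney statistic — the proportion of (positive, negative)
pairs ranked correctly, ties counted ½ — exactly, which the suite checks to
1e−12 on random tied instances. The rank-based definition was chosen over a
logistic-model fit because it is deterministic and model-free.

The PR curve anchors recall 0 at the precision of the smallest nonempty
prediction set, and AUPRC integrates the PR polyline by trapezoid on the
recall axis. Linear PR interpolation is a simple, reproducible convention;
it can be mildly optimistic between distant operating points, and no
nonlinear interpolation is attempted.

## Synthetic paired measurements

`generate_paired_measurements` emulates a paired accuracy study: disease
status is Bernoulli(prevalence); each test's score is drawn from one of two
class-conditional Gaussians on a latent scale (log₁₀ for viral-load-like
data, logit for probability scores), with means placed so dichotomization at
the analysis cutoff attains the target sensitivity and specificity in
expectation. The truth column is itself a measurement on the same scale,
clipped to the correct side of the cutoff. Defaults — 750 subjects, 32%
prevalence, sensitivity 0.90, specificity 0.95, within-class spread 0.6
log₁₀ units — mirror a mid-sized specimen-comparison study; 0.6 log units is
a realistic between-replicate spread for viral-load assays.

What the generator does *not* emulate: correlated errors between paired
tests beyond shared truth status, heavy-tailed or bimodal score
distributions, assay limits of detection/quantification, and
missingness that is informative rather than completely at random. Tests
passing on this synthetic data therefore validate the computational
pipeline, not the behaviour of any particular real assay.

## Numerical choices

* Boundary values classify positive (`value ≥ cutoff`), matching the
  virologic-failure convention; 0/1-coded variables at cutoff 0.5 round-trip
  unchanged.
* All internal computation is on proportions (simple rates are kept as exact
  `Fraction`s, so complement identities like FPR + specificity = 1 hold
  exactly); percent scaling by 100 happens only at rendering.
* Rendering rounds half-up (170.97 → 171.0 at one decimal), not banker's,
  matching conventional table formatting; rounding is applied only at render
  time. The tidy CSV export writes floats at 17 significant digits so a
  round trip through the file is bit-exact (read back with pandas
  `float_precision="round_trip"`).
* The acceptance script scales its seeded checks to 500 random ROC
  instances, all Clopper–Pearson pairs with n ≤ 25, all 2×2 tables with
  cells in {0..6}, and one simulation of 10⁵ subjects — sizes at which every
  property is already exercised across its edge cases while the whole script
  completes in seconds.

## Known limitations

* The Youden, F-score and kappa interval constructions are asymptotic or
  pragmatic (see above); bootstrap, Bayesian or delta-method alternatives
  are out of scope.
* Only binary truth is supported (no multi-category references, no weighted
  kappa), and predictive values are not re-adjusted to an external
  prevalence.
* The published reference table this package reproduces prints one
  internally inconsistent interval (its false-discovery-rate CI corresponds
  to a different denominator than the FDR point estimate); the package
  always uses the measure's own denominator n₁ = a+b.
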