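# Methods

## The testing problem

Given a response `Y` (length n), a covariate of interest `X` (n×d,
usually d=1) and control covariates `Z` (n×p, normally including an
intercept), we test H0: β = 0 in the linear model

    Y = Xβ + Zθ + ε,

making **no** assumption on θ and only one assumption on the noise: the
entries of ε are exchangeable.  No moments, no symmetry, no normality —
Cauchy noise, log-normal skew and single gross outliers are all admitted.
This matters for high-throughput biological measurements (the motivating
setting is immune-cell proportions regressed on disease status adjusted
for demographics), where residual distributions are routinely heavy-tailed
and skewed and classical F-tests over-reject exactly where discoveries are
claimed.

## The paired-permutation construction

For each of B permutations π drawn i.i.d. uniformly from S_n, two
augmented models are fitted and compared:

    M_orig = ℳ(Y, X,   [Z, Z_π])        M_perm = ℳ(Y, X_π, [Z, Z_π])

The augmentation by the permuted controls Z_π puts X and X_π on equal
footing.  An evaluation functional ω (smaller = better fit) turns each
pair into a win/loss, and

    p = (1 + #{b : ω(M_orig^b) ≥ ω(M_perm^b)}) / (1 + B).

If ℳ is (1) invariant to shifting Y by anything in span([Z, Z_π]) and
(2) invariant to jointly permuting the rows of its arguments, then
P(p ≤ α) ≤ 2α in finite samples for every θ.  Simulations here (and the
shipped acceptance checks) show the nominal level α is respected in
practice without the factor of two.  Ties count toward the numerator with
exact floating-point equality — the conservative direction.

Both conditions are *checkable*, and `robustpalmrt.verify.check_conditions`
ships as a public utility so custom fitters can be certified before their
p-values are trusted.

## Fitters

All fitters return a `FitSummary`: an estimated residual scale ŝ plus the
**sorted** residual vector.  Sorting is the mechanical device that
enforces row symmetry; every solver depends on Y only through
span-determined least-squares projections, which enforces shift
invariance.

* **OLS** — projection residuals.  ŝ is the scaled MAD of the residuals of
  the preliminary regression Y ~ [Z, Z_π] (needed only when a scale-aware
  evaluator is attached; it is `None` when that MAD is degenerate).
* **Huber** (the robust default) — a three-stage composite:
  1. a full robust regression of Y on [Z, Z_π] alone, by IRLS with the
     scale re-estimated as 1.4826·MAD of the current residuals at every
     iteration (MASS-style), initialized at OLS;
  2. ŝ frozen at the MAD of the final preliminary residuals;
  3. a fixed-scale Huber IRLS of Y on [X, Z, Z_π] with weights
     w_i = min(1, δ/|r_i/ŝ|).
  Because ŝ is computed from the controls alone it is identical for the
  original and permuted member of each pair, so their scores are
  comparable; under the alternative it is mildly inflated, which pushes
  residuals into the quadratic region and *helps* power.
  Defaults: δ = 1.345 (95% normal efficiency), max_iter = 50,
  tol = 1e-6 on the relative coefficient change.  Non-convergence warns
  rather than fails — the test stays valid for any deterministic ℳ.
* **Quantile** — check-loss regression at a single quantile (default the
  median), preliminary-MAD scale as above.

The MAD consistency constant defaults to 1.4826 (normal-consistent, the
convention of the robust-regression software δ=1.345 is calibrated for);
`mad_constant=1.0` gives the raw MAD.

## Evaluators

* `l2` — Σ r², `l1` — Σ|r| (scale-free),
* `huber` — Σ ρ_δ(r_i/ŝ), the scaled Huber norm.

All are symmetric in the residuals, so ω∘ℳ inherits row symmetry.  The
named combinations of the simulation study are compositions: OLS-L2 (the
plain permutation ANOVA), OLS-Huber (robust evaluation of a least-squares
fit), Huber-Huber (the robust default).  Separating fitting from
evaluation is deliberate: robust *evaluation* turns out to carry most of
the power gain under heavy tails, regardless of how the model is fitted.

## Dispersion testing

To test whether a binary covariate widens the response distribution
(rather than shifting it), each model is summarized by two quantile
regressions of Y on [X, Z, Z_π] at q_low = 0.10 and q_high = 0.90.  The
fitted conditional 80% inter-quantile spread of subject i is
ŷ_i(q_high) − ŷ_i(q_low) ≥ 0, and

    ω = −log( mean spread among cases / mean spread among controls ),

so smaller ω means relatively more case dispersion and the paired
comparison is one-sided for increased case dispersion (a two-sided
variant, ω = −|log ratio|, sits behind a flag).  Group means pair the two
fits by subject index; since the mean is sum-based this equals any
order-statistic pairing.  The test is markedly conservative under the
null — its null rejection rate at α = 0.05 sits near zero — which the
acceptance checks confirm rather than correct.

## Confidence intervals

Inverting the family of tests of Y* = Y − Xβ* gives an interval with
guaranteed coverage ≥ 1 − 2α (empirically ≈ 1 − α).  One `PermutationSet`
is reused across the whole β* grid so the p-value profile is a stable
function of β*; the default grid is 401 equally spaced points spanning
the OLS estimate ± 10 OLS standard errors.  The reported interval is the
convex hull of the non-rejected grid points, and the full profile is
returned so a user can detect a disconnected acceptance region.  If every
grid point is rejected the interval is flagged empty rather than raising.

## Baselines

* Partial F-test of Y ~ Z versus Y ~ X + Z with (d, n−d−p) degrees of
  freedom (for d=1 identical to the squared-t test).
* Koenker-studentized Breusch–Pagan test: OLS of Y on [X, Z], auxiliary
  OLS of the squared residuals on an intercept plus X (the default, since
  the dispersion model puts heteroskedasticity in X; `aux="xz"` uses the
  full design), statistic n·R² against χ².  The studentized form is
  computed through statsmodels.

## Numerical design

* Every least-squares subproblem is solved on an orthonormal basis of the
  design's column span, obtained once per test by batched SVD with a
  relative singular-value cutoff of 1e-9.  [Z, Z_π] is *always* rank
  deficient when Z contains an intercept (its permuted copy is itself);
  working on the span makes fits depend only on the span, which is
  exactly what shift invariance requires, and keeps the per-iteration
  normal equations well-conditioned.  The X column is appended to the
  control basis by Gram–Schmidt rather than a second SVD.
* The response is pre-projected onto the orthogonal complement of the
  design span before any iterative fit.  Mathematically a no-op for the
  residuals; numerically it makes shift invariance hold to ~1e-14
  instead of ~1e-5 (floating-point error is not amplified through the
  iterations), so the certification suite can use a tight 1e-6 tolerance.
* Quantile regressions are solved by a primal-dual interior-point method
  (Mehrotra predictor–corrector) on the dual linear program
  max y'd s.t. U'd = (1−q)U'1, 0 ≤ d ≤ 1 — the Frisch–Newton formulation
  standard in quantile-regression software.  It closes the duality gap to
  1e-8 in ~8–13 iterations, each a k×k batched solve across all B
  permutations at once, and its deterministic iteration doubles as the
  tie-breaking convention when the minimizer is non-unique.  In
  cross-checks against statsmodels' IRLS solver its check loss is never
  higher.
* Shipped fitters expose a `fit_pair_batch` path vectorized over the B
  permutations (one SVD + batched BLAS per test) beside the generic
  per-pair `fit`; tests assert both paths agree to ~1e-9.
* Degeneracy is detected relatively, not exactly: a preliminary-fit MAD
  below 1e-10·max|Y|, or a group-mean fitted spread below 1e-10·sd(Y),
  raises a degenerate-scale/dispersion error instead of silently flooring
  the scale (a floor would quietly change ω).  Such inputs mean Y is
  numerically in the control span and the statistic is meaningless.

## Synthetic data and the study harness

The generators reproduce the benchmark conditions the tests are
characterized under:

* Design: Z has an intercept column; all other entries of [X, Z] are
  i.i.d. Cauchy(0,1) by default (normal, t3 and a balanced ±1 two-level
  "ANOVA" layout are also available).  Heavy-tailed covariates make the
  problem deliberately hard for projection-based methods.
* Error laws: `normal`, `t3`, `cauchy`, `lognormal` (exp of a standard
  normal), and `multinomial_normal` — n−1 standard normals with one
  uniformly chosen entry replaced by N(±10⁴, 1), sign equiprobable: a
  single catastrophic outlier.
* Location model: Y = Xβ + ε with θ = 0, justified by the proven shift
  invariance (a nonzero-θ end-to-end test guards the claim).
* Dispersion model: Y_i = (1 + βX_i)ε_i with balanced binary X (n/2
  cases, randomized order); β = 1 doubles the case noise scale.
* Defaults mirroring the study conditions: α = 0.05, B = 999 for data
  analysis; the Monte-Carlo harness and acceptance checks use B = 199
  and 500 replicates per cell at n = 100, p = 6 — sizes chosen so a full
  five-law type-I sweep runs in minutes on one core while keeping the
  binomial standard error at β=0 near 0.01.
* Per-replicate seeds are spawned from a scenario master seed
  (`SeedSequence.spawn`), so results are bit-identical between serial and
  parallel execution and across machines.

Effect-size calibration finds the β at which the partial F-test attains a
target power (the fair yardstick for power comparisons): bisection against
a power curve evaluated with common random numbers.  Residualizing X and ε
on Z reduces each replicate's F statistic at any β to a rational function
of three scalars, so the shared-draw power curve is exact and cheap;
tolerance 0.02, 2000 replicates per evaluation.

What the generators do *not* emulate: dependence across observations,
heteroskedasticity beyond the binary dispersion model, non-linear
confounding, or the compositional constraints of real proportion data.
Passing tests certify finite-sample level and relative power under
exchangeable noise with the stated laws — not robustness to violations of
exchangeability itself, which is the method's one real assumption.

## Known limitations

* The location test's guarantee is P(p ≤ α) ≤ 2α; the observed level is
  ≤ α in all study conditions here, but pathological evaluators can make
  the factor of two real.
* The dispersion test is conservative (null rejection ≈ 0.004 at
  α = 0.05, n = 100, normal noise), trading level tightness for validity.
* CI inversion assumes a scalar covariate of interest and reports the
  hull of a gridded acceptance region; resolution is limited by the grid
  and coverage by the 1/(B+1) p-value floor.
* Z must be of modest dimension (the augmented design has 2p control
  columns); no high-dimensional or multivariate-response support.
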