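# Methods

## Model and likelihood

The package analyzes a two-arm trial whose outcome is an ordinal scale with
K categories, stored as a 2×K count table. Writing γ_j(x) for the
probability of an outcome at or better than category j in arm x (x = 1 for
treatment), the proportional-odds (PO) model is

    logit γ_j(x) = α_j + β·x ,  j = 1..K−1,  α_1 < … < α_{K−1}.

"Better" is defined by the scale's orientation metadata (`lower_better` for
mRS-style scales, `higher_better` for GOS-E-style scales); internally the
table is reordered best-first, so exp(β) — the common odds ratio — is always
benefit-oriented. The likelihood is the count-weighted multinomial with cell
probabilities given by adjacent differences of inverse-logit cumulative
probabilities, with the convention 0·log 0 = 0.

The slope is shared across all K−1 dichotomizations; that sharing is the PO
assumption, and the MLE of β acts as a weighted average of the K−1 observed
cut-point log odds ratios. Three nested fits drive all likelihood-ratio
tests: the null (β = 0, closed form: pooled multinomial), the PO fit, and
the saturated fit (separate multinomials per arm, closed form). The LR test
of the treatment effect compares PO to null (df = 1); the LR test of the PO
assumption compares saturated to PO (df = K−2, since the saturated model has
2(K−1) free parameters and the PO model K). For K = 2 the PO model is
saturated and the assumption test is refused.

## Fitting: numerical choices

- Newton–Raphson in (α, β) with analytic gradient and Hessian (per-arm
  tridiagonal in the linear predictors, assembled by the chain rule).
  Starting values: pooled empirical cumulative logits, β = 0. Step-halving
  rejects any step that breaks threshold ordering or decreases the
  log-likelihood. Convergence: max |gradient| < 1e−9, at most 200 iterations.
- If Newton fails (singular Hessian, no acceptable step), a BFGS fallback
  runs on the unconstrained reparameterization α_1 free, increments as
  exponentials.
- The variance matrix is the inverse observed information (the Newton
  Hessian at the optimum); CIs are Wald on the log-OR scale. Profile
  likelihood CIs are out of scope — Wald intervals match common trial
  reporting.
- Complete separation is flagged when |β| > 15 at the optimum; the fit is
  marked non-converged, the Wald p is reported as NaN, and the cOR CI is
  (0, ∞). Likelihood-ratio p-values remain usable.
- All chi-square reference distributions are asymptotic; no small-sample or
  continuity corrections anywhere (consistent across tests, including the
  2×K Pearson χ² at K = 2).
- Categories with zero pooled count make the likelihood boundary-degenerate;
  they are never dropped silently. `drop_empty_categories` removes them
  explicitly, and the simulation engine calls it per replicate, logging the
  count of affected replicates, so degrees-of-freedom changes are traceable.

## Competing tests

- **Mann-Whitney U**: computed from the grouped counts with midranks. The
  two-sided p uses the normal approximation with tie-corrected variance
  n₁n₂/12·[(N+1) − Σ(t³−t)/(N(N−1))] and no continuity correction: ties
  dominate ordinal trial data, making the exact distribution impractical and
  the correction negligible at trial sizes. The approximation error against
  the exact permutation distribution is O(1/n) — about 0.02 in p at n = 30
  per arm, under 0.005 at n = 300 per arm (both verified in the test suite);
  interpret small-sample p-values accordingly.
- **Linear-by-linear trend** (Cochran-Armitage type): M² = (N−1)r² with r
  the Pearson correlation between arm indicator and category scores, df = 1.
  Default scores 0..K−1; any affine transform gives the identical statistic.
  The (N−1) scaling is fixed by the classical M² definition and verified
  against the permutation oracle, rather than claimed to match any
  particular legacy implementation.
- **Pearson χ²** on the 2×K table (df = K−1), no Yates correction; a
  warning annotation fires when an expected cell is below 5, the usual
  trigger for merging sparse adjacent categories (merged labels join with
  "+", e.g. "0+1").
- **Welch t** on integer scores 0..K−1 expanded from counts; Welch rather
  than pooled variance for robustness to unequal spread.
- **Hybrid pretest strategy** (PO-assumption LR at 0.05, then χ² if
  rejected, else PO-LR): implemented *only* to reproduce its invalidity.
  Its result always carries an inflation warning, and the CLI hides it
  behind `--unsafe-hybrid`.

## Cut-point diagnostics

Each of the K−1 dichotomizations yields a 2×2 table, an OR oriented
treatment-over-control on the "at or better" side, a Woolf log-SE
√(Σ 1/cell) and a 95% Wald CI. Zero cells: the default Haldane–Anscombe
rule adds 0.5 to all four cells of the affected 2×2 only (plots need finite
CIs); a `strict` mode flags the entry undefined instead, so inference never
silently depends on the correction. CIs are unadjusted for multiplicity —
the plot is descriptive. Labels render on the clinical scale
("0-2 vs 3-6" style). The bundle (cut-point ORs + common OR with CI + PO
test) serializes to JSON and tidy CSV.

## Win statistics and utilities

Win/tie/loss probabilities are computed exactly from the counts (the O(n²)
pair sum collapses to a K-term sum); the probabilistic index, net benefit,
win ratio and win odds follow by identity. CIs are percentile bootstrap
(default 2,000 within-arm multinomial resamples, seeded) — a single uniform
mechanism covering all four measures; closed-form variances are not
provided. A zero loss probability reports an infinite win ratio with an
unbounded CI.

Utility summaries contrast mean utilities (Σ p̂_gj·u_j) between arms. The
standardized difference divides by the pooled both-arms per-observation
utility SD (ddof = 1) — one defensible choice among several, recorded in
the output metadata — and is invariant to affine rescaling of the value
set. CIs by seeded percentile bootstrap (default) or delta method. Utility
value sets are always user-supplied files; the package ships none, because
published sets vary by country, instrument and population.

## Simulation engine and study conditions

Trials are independent per-arm multinomial draws. One master seed spawns a
`SeedSequence` substream per replicate, so estimates do not depend on
evaluation order. Replicates where a strategy errors count as
non-rejections and are tallied (`n_failed`); replicates needing category
drops are tallied (`n_degenerate`). Pooled-empty categories are dropped
before *every* built-in strategy, not only the model-based ones: χ² also
requires positive pooled cells and the rank tests are invariant to empty
categories, so the uniform rule changes nothing while staying simple (at
the default null, 5 categories at 0.2 and n = 100 per arm, an empty cell
has probability ≈ 4e−20).

The PO-shift family generates exact-proportionality alternatives: treated
cumulative odds are θ times control cumulative odds at every cut, so every
population cut-point OR equals θ by construction. The power-similarity
experiment uses a uniform 5-category control with this family over a
log-cOR grid (the natural reading of "right-skewed to left-skewed with log
cOR from negative to positive"), per-arm n = 50.

The named scenario library fixes the shift-vs-nonshift contrast:
scenario 1 is the exact shift at θ = 2.7; scenario 3 is uniform control vs
the palindromic (0.30, 0.15, 0.10, 0.15, 0.30) — palindromy about a uniform
control forces the population common OR to exactly 1 (verified by fitting
the population frequencies), while the arms differ sharply. Scenario 2 (a
"semishift" with the positive trend concentrated in middle categories) has
no canonical published distribution; the library ships a representative
(0.32, 0.30, 0.20, 0.10, 0.08) labelled as such, and no test asserts its
common OR. Default per-arm sizes: 100 for the null pretest experiment, 200
for the shift-vs-nonshift contrast, 50 for the power-similarity grid;
headline experiments use 20,000 replicates (Monte-Carlo SE ≈ 0.0015 at
rates near 0.05), exploratory runs 2,000–5,000.

What the generator does *not* emulate: covariates and stratified
randomization, missing outcomes, non-multinomial sampling (e.g. blocked
designs), and misclassification of outcome assessors. Passing simulation
tests therefore validate the test statistics and the selection-effect
mechanism of the pretest strategy, not robustness to those real-data
features.

## Known limitations

- Two arms only; no covariate adjustment or partial-proportional-odds
  models.
- Wald (not profile) CIs; asymptotic p-values throughout — small trials
  with heavy ties deserve exact or permutation methods this package does
  not provide.
- The Mann-Whitney p is an approximation whose error is visible below ~50
  per arm (quantified above).
- Bootstrap CIs for win statistics are percentile-type; no BCa correction.
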