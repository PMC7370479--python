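# Methods

## Model and estimators

The data for one prevalence estimation problem are three independent
binomial counts: `x ~ Bin(n, AP)` from applying the test,
`x_se ~ Bin(n_se, Se)` from a sensitivity validation study and
`x_sp ~ Bin(n_sp, Sp)` from a specificity validation study, with
`AP = Se·π + (1−Sp)(1−π)`.

**Rogan–Gladen.** The point estimate inverts the AP identity at the MLEs;
values outside [0, 1] are truncated. A dataset is *excluded* when
`1 − Ŝp ≥ Ŝe` (strict condition: equality excludes), because a test whose
estimates say it performs no better than chance would not be used; the
adjustment is undefined or direction-reversed there. Retained datasets are
labelled case 1/2/3 by the raw estimate lying in [0, 1], below 0, or above
1; the boundary values 0 and 1 themselves are case 1 (the non-strict
conditions `1 − Ŝp ≤ ÂP ≤ Ŝe` hold, no truncation is needed). All
boundary comparisons are arranged so that the classification, the sign of
the raw estimate and the interval transforms use the identical floating
point expressions (`fp = 1 − Ŝp`, `denom = Ŝe − fp`), making the three
mutually consistent to the last bit; equal rational proportions map to
equal doubles, so exact-boundary counts classify correctly.

**Exact intervals on the AP scale.** Clopper–Pearson by Beta-quantile
inversion; Sterne by inverting the minimum-likelihood-ordering exact test;
Blaker by inverting the combined-tails (acceptability) test. Test
inversion brackets each endpoint with a 129-point scan and bisects to
1e−8; because Sterne acceptance sets can in principle be non-contiguous,
the reported interval is the enclosing interval of the acceptance set. The
AP-scale interval is mapped to the prevalence scale through the increasing
linear adjustment with `Ŝe`, `Ŝp` treated as known, then truncated to
[0, 1] (truncation before or after the map commutes).

**Wald-type interval.** The default `wald_rogan_gladen` interval is the
normal-approximation interval that maps the binomial variance of ÂP
through the adjustment with `Ŝe`, `Ŝp` treated as known — the construction
used alongside the exact methods in the comparison, and one that shares
their severe under-coverage. The full delta-method variance of Rogan and
Gladen, which adds `π̂²·Ŝe(1−Ŝe)/n_se + (1−π̂)²·Ŝp(1−Ŝp)/n_sp` (weights at
the truncated point estimate), is available via
`include_validation_uncertainty=True`; in our simulations it attains
roughly nominal mean coverage and is therefore *not* the variant whose
coverage distribution the validation study characterises as deficient.

**Lang–Reiczigel adjusted Wald interval.** Pseudo-observations are added
before forming proportions: `z²/2` successes and failures to the
application sample (the Agresti–Coull adjustment; denominator `n + z²`)
and one success and one failure to each validation sample (Beta(1, 1)
posterior-mean updating; denominators `n_se + 2`, `n_sp + 2`). The
adjusted Rogan–Gladen point (truncated to [0, 1] before use in the
variance weights) gets a delta-method interval with the adjusted values
and denominators, truncated to [0, 1]. The constants sit in one
configuration object (`LangReiczigelAdjustment`) so they can be changed
without touching callers; the choice is guarded empirically by the
coverage results (mean per-scenario coverage ≈ 95.8% on the full design,
slightly conservative). In the vanishingly rare event that the *adjusted*
test drops to chance level the single-dataset API raises; the batch path
emits a missing interval, which coverage summaries drop from their
denominators.

**Bayesian model.** Priors π ~ Beta(1, 1) and validation-informed
Se ~ Beta(x_se+1, n_se−x_se+1), Sp ~ Beta(x_sp+1, n_sp−x_sp+1); likelihood
`x ~ Bin(n, Se·π + (1−Sp)(1−π))`. Sampling is by data augmentation: the
latent number of truly diseased among test-positives (T1) and among
test-negatives (T2) makes all full conditionals Binomial or Beta, giving
an exact Gibbs sweep with no tuning. The sampler is vectorised across
chains *and* datasets (batches of up to 4,000 datasets × 3 chains as one
array program), which is what makes fitting tens of thousands of datasets
feasible on one CPU.

*Run lengths.* Default: 3 chains, 5,000 discarded sweeps each (4,000
burn-in plus 1,000 sweeps discarded for comparability with samplers that
spend a warm-up phase adapting — a pure Gibbs sampler has nothing to
adapt), and ≈20,000 retained draws pooled across chains (6,667 per chain).
Chains start overdispersed (π⁰ ∈ {0.1, 0.5, 0.9}, Se⁰/Sp⁰ at prior means).
Convergence is monitored by the Gelman–Rubin PSRF on π (threshold 1.05); a
failing dataset is re-run once with doubled retained length and flagged
`converged=False` if still failing. Effective sample size uses the
autocorrelation-sum estimator (chain-averaged autocorrelations summed
until they fall below 0.05), cross-checked against `arviz.ess`; it is
reported, never used for gating. ESS varies strongly with the dataset
(≈2,600 on the small worked example, ≈9,000 on large-n datasets).

*Summaries.* Point estimate: mean of the pooled draws (minimum-MSE under
squared error). Interval: 95% HDI — the shortest window over the sorted
pooled draws containing ⌈0.95·N⌉ of them; ties broken at the lowest start
index, so the result is deterministic given the draws.

## Synthetic-data generator

Scenario truth: Se, Sp ~ U(0.6, 1), π ~ U(0, 1) independently; validation
sizes drawn with equal probability from {50, 100, 200, 500, 1000, 2000,
5000}; n uniform on the integers 50..2000 inclusive (a continuous draw
with rounding would bias the endpoints). Because Se, Sp > 0.6 the truth
always satisfies the adjustability conditions. Replicate datasets are the
three binomials above.

Reproducibility: every scenario owns two deterministic substreams keyed by
`(seed, scenario_id, stage)` — stage 0 draws its parameters, stage 1 its
replicate count vectors — so scenario k is byte-identical no matter how
many scenarios or replicates the study draws, and any dataset can be
regenerated in isolation from `(seed, scenario_id)` by indexing its
replicate position. Per-replicate substreams were rejected: constructing
10⁶ generator objects costs tens of seconds and would dominate the
frequentist-only full-design runtime.

What the generator does *not* emulate: clustered or stratified sampling,
overdispersion, finite-population effects, correlated design parameters,
or validation panels unrepresentative of the application population.
Passing tests therefore say nothing about those failure modes; they
validate the estimators under independent binomial sampling with uniform
truth.

## Validation metrics

Estimation error is `point − π_true` per dataset and method, carrying the
case label. Coverage is computed per scenario as the fraction of retained
replicates whose interval contains π_true (excluded datasets never enter
the denominator). Interval length is `upper − lower` after truncation.

The comparison between estimators uses equal-variance Deming (orthogonal)
regression: slope `(s_yy − s_xx + √((s_yy − s_xx)² + 4 s_xy²)) / (2 s_xy)`,
intercept through the means, Pearson r on the same pairs. The slope CI is
a leave-one-out jackknife (computed by downdated moment sums, O(N)); the
study it reproduces does not state its CI method, so widths — not the
point estimate — may differ from the original. The residual-error
regression is OLS of the error on the six z-transformed truth/design
variables plus all 15 pairwise interactions (22 coefficients), per
estimator, with z-scores taken over the analysis set.

For Sterne and Blaker, large-scale coverage uses a test-inversion
shortcut: the transformed interval covers π_true iff the exact test does
not reject the apparent prevalence implied by it,
`a* = (1 − Ŝp) + π_true (Ŝe − (1 − Ŝp))` — one p-value per dataset instead
of two bisections. The event that `a*` falls exactly on an interval
endpoint has probability zero.

## Problem sizes used in tests and the acceptance script

Frequentist-only quantities (truncation rate, exclusion count,
Lang–Reiczigel coverage) use the study's full design, 1,000 scenarios ×
1,000 replicates, fully vectorised. MCMC-based comparisons run at reduced
scale with shortened chains (3 × [1,000 burn-in + 4,000 retained]): 200
scenarios × 100 replicates for the error and length regressions, 100 × 200
for HDI coverage. Sterne/Blaker coverage behaviour is checked on a
200-scenario subset of the full design via the p-value shortcut. These
sizes are the package's chosen trade-off between Monte-Carlo error and
runtime; at them, heavy-tailed statistics (the truncation percentage, the
exclusion count, and correlations involving interval lengths in
borderline scenarios where a clipped length-1 adjusted interval meets a
narrow HDI) retain visible seed-to-seed variability, which the test
tolerances inherit.

## Numerical choices and degenerate inputs

- Bisection tolerance 1e−8 on the binomial parameter; pmf ties in the
  minimum-likelihood ordering broken with a 1e−10 relative tolerance.
- Beta draws keep all posterior draws strictly inside (0, 1); prior means
  used for initialisation are clipped to [1e−6, 1−1e−6].
- Retained draws are stored float32 (memory ∝ datasets × chains × draws);
  summaries accumulate in float64.
- Zero denominators (`Ŝe + Ŝp = 1`) raise rather than return infinities;
  they are unreachable for retained datasets.
- PSRF of k identical chains is √((S−1)/S) < 1: with zero between-chain
  variance the within-chain degrees-of-freedom correction dominates, so
  values slightly below 1 are expected and pass the 1.05 threshold.
- CSVs are written with repr-faithful floats and read back with the
  round-trip parser, so case labels and classifications survive write/read
  exactly.

## Known limitations

- The Sterne/Blaker interval search can in principle miss an acceptance
  sub-interval narrower than the 1/128 scan grid; no such case is known
  for the levels used here.
- The Lang–Reiczigel pseudo-count constants follow the published
  adjustment (z²/2 for the application sample, Beta(1,1) updating for the
  validation samples); they are configuration, and alternative constants
  change coverage by fractions of a percentage point on the full design.
- The Deming slope jackknife CI assumes approximately normal slope
  estimates; for the ~2×10⁴-point comparisons used here that is benign.
- Single-CPU design throughout; no parallel backends.
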