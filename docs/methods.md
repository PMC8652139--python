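# Methods

## Activity inference by T-score

The T-score treats a directional gene signature as a measurement
instrument for the activity of the regulator that produced it. For one
sample, let U and D be the centered expression values of the up- and
down-signature homologs present in the matrix. The score is the
equal-variance (Student, never Welch) two-sample *t* statistic of U
against D, reported through the equivalent form d·TINV(p, df) with
df = |U| + |D| − 2. At an exact mean tie, d is +1 and the score is 0
regardless; `classify_activity` calls a sample active only for a strictly
positive score, so 0 is inactive. Raw per-sample p-values are reported
with no multiple-testing correction; they describe each sample's contrast
on its own. A minimum of two genes per direction is enforced (the pooled
test is undefined below that), and a zero pooled variance is a hard
degenerate-input error rather than an infinite score.

### Preprocessing conventions

* Probe-level matrices are collapsed to gene level by keeping, per gene,
  the probe with the largest sample standard deviation (ddof = 1); ties
  break to the lexicographically first probe id. Probes without a unique
  gene mapping are dropped and counted.
* Each gene row is then centered to median zero across samples; for even
  sample counts the median is the mean of the two middle order statistics,
  which makes centering idempotent. Collapse happens before centering so
  the centering describes the gene-level values actually tested; the
  reverse order would center probe rows that are later discarded.
* Signatures are projected through an ortholog map by set image and
  intersection with the matrix rows. Symbols are matched case-sensitively
  after whitespace trimming. A homolog reachable from both directions is
  excluded from both (many-to-many maps make such collisions routine;
  exclusion preserves disjointness), and per-direction drop counts are
  reported so silent signature shrinkage is visible.

## The three-node path model

Variables: two exogenous regressors x₁, x₂ (T-scores and/or expression of
the upstream regulators) and one endogenous reporter y. Free parameters in
the full model: the two regression paths γ₁₁, γ₂₁, the exogenous variances
and covariance, and the residual variance ψ — six parameters against six
unique covariance moments, so the full model is saturated (df = 0). Any of
{γ₁₁, γ₂₁, cov(x₁,x₂)} may be fixed to zero, each adding one df. There is
no mean structure: the model concerns relationships, and all inputs are
centered implicitly by using covariances.

Estimation minimises the ML discrepancy
F = log|Σ(θ)| + tr(S Σ(θ)⁻¹) − log|S| − 3 with S the sample covariance
(divisor n − 1) and uses the Wishart-convention multiplier
T = (n − 1)·F_min. The discrepancy factorises into an exogenous-block term
and a conditional term log ψ + (s_yy − 2γ's_xy + γ'S_xx γ)/ψ, so every
constraint pattern has an exact closed-form minimiser: the free paths are
the (restricted) regression coefficients of y on the free regressors, ψ is
the corresponding residual variance, and the exogenous block is S_xx or
its diagonal. The implementation is therefore non-iterative; the test
suite cross-checks it against an independent generic quasi-Newton
minimisation of the same discrepancy.

Standard errors come from the inverse expected information
I_jk = (n−1)/2 · tr(Σ⁻¹ ∂Σ/∂θⱼ Σ⁻¹ ∂Σ/∂θₖ) with analytic derivative
matrices; per-parameter tests are two-sided Wald normal, the standard SEM
practice. Because the paths are unstandardized regression coefficients
(not correlations, despite occasional loose usage of that word for path
diagrams), the results object also reports standardized coefficients
(γ · sd(x)/sd(y)) for scale-free interpretation.

### Fit indices

* **Chi-square**: T against χ²(df). For the saturated model T is zero up
  to round-off and the indices are set to their perfect-fit values exactly
  (RMSEA 0, CI (0,0), CFI 1, TLI 1) rather than letting 1e−15 of float
  noise leak through.
* **RMSEA** = sqrt(max(T − df, 0)/(df (n−1))); the 90% CI inverts the
  noncentral χ² CDF in the noncentrality parameter by bisection to 1e−8,
  truncating at zero. Conventional reading: < 0.05 close fit, 0.05–0.10
  marginal, > 0.10 poor.
* **CFI** = 1 − max(T − df, 0)/max(T_b − df_b, T − df, 0) and
  **TLI** = ((T_b/df_b) − (T/df))/((T_b/df_b) − 1), both against the
  independence baseline (diagonal Σ, free variances; its ML solution is
  diag(S), giving T_b = −(n−1) log|R| with R the correlation matrix,
  df_b = 3). TLI at df = 0 is reported as 1 (the ratio form is undefined
  there and 1 matches perfect-fit semantics).
* **SRMR**: root mean square of the standardized residuals
  (s_ij − σ̂_ij)/(sd_i sd_j) over all six unique elements, diagonals
  included — one documented choice among the published SRMR variants;
  < 0.08 is conventionally a very good fit.

All indices are invariant to rescaling any variable by a positive
constant, which is property-tested.

## Elimination bootstrap

The two modes answer slightly different null questions about a designated
target subset of N signature genes:

* The **observed** statistic is always the chosen path-model summary after
  deterministically removing the target subset (default statistic: the
  perturbed regulator's path coefficient; selectable to the other path,
  χ², RMSEA, CFI, TLI or SRMR).
* **Without replacement** replicates remove N genes drawn uniformly from
  the non-target signature genes — "is removing *these* N genes different
  from removing *any* N genes?"
* **With replacement** replicates remove the target subset and refill with
  N genes drawn uniformly without repetition from a background pool
  (excluding current signature members), restoring the original size —
  "do random pool genes replace the information the targets carried?"
  Each refill gene inherits the direction of the removed gene it replaces,
  matched by removal order (sorted gene id); directions are thereby
  preserved in count.

Every replicate recomputes T-scores from the perturbed signature and
refits the path model with the other regulator and the endpoint held
fixed. The empirical p-value is max(count of replicates at least as
extreme, 1)/B under the chosen tail (two-sided uses the doubled smaller
tail count, capped at B), flooring at 1/B — hence 1000 iterations for a
smallest resolvable p of 0.001. Replicates draw from independent seed
substreams (`SeedSequence(seed, spawn_key=(i,))`), so results are
identical whatever the execution order or thread count; the suite checks
prefix-reproducibility across different B. A replicate whose perturbed
signature is degenerate (e.g. a direction left with fewer than two genes)
is excluded and counted; more than 5% failures aborts the run. With
failures, the p-value denominator is the successful-replicate count.

## Synthetic data

`simulate_expression` draws background genes as N(0, noise_sd²) and shifts
up/down signature genes by ±effect_size per unit of a standard-normal
latent activity — the simplest generative model under which the T-score is
a calibrated activity estimate. Defaults (effect_size 1, noise_sd 1;
chained fixture uses effect_size 2 so signs are reliably recoverable at
moderate sample counts) represent a clearly detectable but not extreme
signature response. `simulate_sem_dataset` draws the regressors bivariate
normal with unit variances and correlation `exo_corr` and forms the
endpoint from the structural equation. `make_chained_truth` composes the
two so the whole pipeline can be exercised from files on disk with known
γ's.

What the generators deliberately omit: microarray platform artifacts,
batch effects, count-based RNA-seq noise, correlated background genes, and
signature genes with heterogeneous effect sizes. Passing tests therefore
demonstrate correctness of the computations and calibration under the
stated Gaussian model, not robustness to real-data violations of it.

## Problem sizes and numerical choices

The simulation-based checks use sizes chosen to make Monte-Carlo noise
negligible relative to the tolerances tested: 1000 random input pairs for
the t-statistic identity (1e−10), 200 datasets at n = 500 for parameter
recovery and Wald coverage, 500 replicates for the χ²(1) distribution of
the constrained-model statistic, 25 replicates at n = 500 for the
close-fit medians, and 200 repeated experiments at B = 199 for bootstrap
null calibration. Covariance matrices are rejected as singular when the
smallest eigenvalue is below 1e−10 of the largest; residual variances are
clipped at zero; the RMSEA CI bisection tolerance is 1e−8 on the
noncentrality.

## Limitations

* The model is limited to three observed variables; latent measurement
  models, larger path models and multi-group fitting are out of scope.
* The two bootstrap modes are separate tests; they are not integrated into
  a single combined test.
* The T-score inherits the equal-variance assumption of the Student test;
  strongly unequal group variances distort the score by design (the method
  specifies the pooled test).
* Empirical p-values are resolution-limited at 1/B and are not corrected
  across multiple target sets.
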