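# Methods

## Estimand and data model

The package estimates the causal effect of an exposure (here CRP, in study
standard-deviation units) on a binary outcome (T2DM or T1DM, on the log
odds-ratio scale) from two independent sets of GWAS summary statistics.  Each
instrument is assumed to (1) associate with the exposure, (2) be independent
of confounders of the exposure–outcome relation, and (3) affect the outcome
only through the exposure.  Violations of (3) — horizontal pleiotropy — are
what the penalized/robust weighting and the MR-Egger intercept are there to
detect and contain.

## Harmonization

Outcome records are aligned to the exposure's effect allele: identical
allele pairs are copied through; swapped pairs negate the outcome beta and
complement its effect-allele frequency.  Palindromic variants (A/T, C/G)
cannot be strand-checked from alleles alone; the default policy keeps them
with a logged warning (the shipped instruments contain none), with `drop`
and `error` available.  Variants present in only one table are excluded with
a logged reason rather than treated as errors.  Frequency-based strand
inference is deliberately out of scope.

## Estimators

* **Wald ratio.** θ̂_j = β_Yj/β_Xj with delta-method SE σ_Yj/|β_Xj|, which
  treats the exposure association as precisely estimated — the standard
  first-order approximation when exposure GWAS are well powered.  A literal
  `se_method="literal"` (σ_Yj/σ_Xj) exists purely to audit analyses that
  used that rule; it is dimensionally inconsistent and off by default.
* **IVW.** Fixed-effect weighted mean; SE (Σw)^−1/2; two-sided normal test.
* **Penalty factors.** min(1, 20·p_j) on the χ²₁ tail probability of
  Q_j = w_j(θ̂_j − θ̂_IVW)², referenced to the *unpenalized, non-robust* IVW
  estimate.  The reference choice matters: re-deriving factors from Egger
  residuals is a defensible alternative and gives slightly different
  intercepts; the IVW reference is used everywhere for consistency.
* **Robust fit.** Tukey bisquare, c = 4.685 (95% Gaussian efficiency), IRLS
  with scale = MAD(weighted residuals about zero)/0.6745, convergence when
  the largest coefficient change is < 1e−10, cap 100 iterations (last
  iterate returned flagged unconverged).  If the scale collapses to zero the
  fit is exact for the weighted majority: zero-residual points keep weight 1
  and materially nonzero residuals get weight 0.  Variants whose penalty
  factor underflows to exactly zero are held out of the IRLS (it requires
  positive weights) and recorded with robust weight 0.
* **SEs for penalized/robust variants.** Multiplicative random-effects
  convention: (Σ w_j f_j)^−1/2 × max(1, σ̂), where σ̂² is the weighted mean
  squared standardized residual (robust weights included, n−1 df).  The SE is
  inflated under overdispersion, never deflated.
* **MR-Egger.** Variants oriented to β_X ≥ 0; weighted regression with
  intercept, weights σ_Y^−2 × penalty factors, optional Tukey loss;
  covariance σ̂²_cap (X'WX)^−1 with σ̂_cap = max(1, σ̂); t inference on n−2
  df; 95% CI via the t quantile.  Requires ≥ 3 variants and spread in β_X.
* **Cochran's Q.** Σ w_j(θ̂_j − θ̂_IVW)² on n−1 df, upper-tail χ².

95% CIs on the OR scale use the fixed normal multiplier 1.959964 except for
Egger's t quantile.  With a single instrument every IVW-family method returns
that instrument's Wald estimate.

A note on p-values: the reported two-sided normal p-values follow from the
SEs above and will not agree with analyses whose software derived SEs
differently; the pooled ORs and the Egger intercept are the stable,
comparable quantities.

## Instrument selection

Filters run in order: exposure significance (strict p < 5e−8), outcome
association (removed when p_outcome < 0.05 — strict, so a variant at
p = 0.059 survives while one at 2e−7 is removed), then greedy LD pruning
(visit candidates by ascending exposure p, ties broken lexicographically;
accept when r² with every accepted candidate is < 0.2).  The r² threshold is
a configuration default: the shipped instruments sit at distinct loci, so
any threshold keeps all of them, but it must be chosen deliberately for new
data.  Greedy pruning is not monotone in the threshold for arbitrary r²
matrices (an admitted early candidate can block later ones); it is monotone
for block-structured LD, the regime the property test covers.

## Synthetic-data generator

`simulate_summary_stats` draws, per variant: a true exposure effect
b_j ~ N(0.15, 0.04²) resampled until |b_j| > 1e−3 (a simulator constraint
keeping Wald ratios defined, not an estimator fix); a direct effect
α_j ~ N(μ_α, σ_α²) independent of b_j, so InSIDE holds by construction; and
observed β_Xj = b_j + N(0, 0.015²), β_Yj = θ·b_j + α_j + N(0, 0.012²) with
θ = 0.11 by default.  Magnitudes mirror the CRP instrument table; the
effect allele is coded as the exposure-raising allele (positive b), the
field's reporting convention, which keeps the sign of the Egger intercept
aligned with μ_α (orientation flips negate a flipped variant's direct
effect).  Alleles come from non-palindromic pairs; p-values are two-sided
normal; outcome betas are simulated directly on the log-OR scale — no
individual-level genotypes, LD, sample overlap, or winner's-curse selection
are modelled, so recovery results validate the estimators' algebra and
sampling behaviour, not robustness to those real-data complications.

One seeded stream is consumed variant by variant in fixed order, so growing
`n_variants` preserves earlier variants.  `recovery_study` spawns
per-scenario, per-replicate seeds from a single SeedSequence and reports
bias, empirical SE, RMSE, 95% CI coverage, and rejection rate (plus the mean
Egger intercept); problem sizes used in the shipped validation are 50–100
variants × 200–500 replicates, ample for the ~0.005-wide Monte-Carlo
tolerances asserted.

## Known limitations

* No weighted-median/mode estimators, multivariable or bidirectional MR,
  weak-instrument corrections, or correlated-instrument generalized IVW.
* LD must be supplied (long or square TSV); it is never computed from
  genotypes, and no proxy lookup replaces pruned variants.
* Penalty-factor reference (IVW vs Egger residuals) and the LD threshold are
  conventions; both are explicit in configuration and documented above.
* Egger inference on very few instruments (n = 3, 4) has 1–2 residual
  degrees of freedom; its intercept CI is wide and its t-based p-values
  should be read qualitatively.
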