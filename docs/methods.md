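# Methods

## Reliability model

Probe reliability is the intraclass correlation of repeated β-value
measurements under a two-way random-effects model with k = 2 raters
(measurement occasions, e.g. two array platforms) and absolute
agreement — ICC(A,k) in the McGraw–Wong taxonomy:

    y_ij = μ + r_i + c_j + e_ij,   i = 1..n subjects, j = 1..2 raters
    ICC(A,k) = σ_r² / (σ_r² + (σ_c² + σ_e²)/k)

estimated from the ANOVA mean squares as
(MSR − MSE) / (MSR + (MSC − MSE)/n). The model choice matters:
absolute agreement counts a systematic platform offset (σ_c²) against
reliability, whereas Pearson's r or a consistency-type ICC would not.
Both ICC and Pearson r are reported per probe so the difference is
visible in the output, and the three mean squares are exposed for
auditing.

Numerical/degenerate conventions:

- Fewer than 3 complete pairs → `insufficient_n`, ICC missing.
  Missing cells are handled by complete-pairs deletion per probe (the
  policy is recorded in the table metadata; no imputation).
- Zero total variance → `degenerate`, ICC undefined.
- Negative estimates are reported as computed; empirical per-probe
  ICCs genuinely extend below zero and clipping would bias summaries.
- The ANOVA denominator estimate MSR + (MSC − MSE)/n can turn
  nonpositive for noise-dominated data at small n (about 1% of pure
  white-noise n×2 matrices). There the coefficient is undefined
  (the raw ratio would exceed 1); such probes are flagged
  `degenerate` rather than reported. Algebraically the denominator
  minus the numerator equals ((n−1)·MSE + MSC)/n ≥ 0, so whenever the
  denominator is positive the estimate is ≤ 1, with equality exactly
  when MSE = MSC = 0.
- Categories: poor < 0.4 ≤ fair < 0.6 ≤ good ≤ 0.75 < excellent.
  Boundary handling is half-open as written; 0.75 itself is "good".
- M values: M = log2(β/(1−β)), with an offset ε = 1e-6 applied only at
  β ∈ {0, 1}; interior values are left exact.

## Twin ACE decomposition

Trait values are standardized per probe (mean 0, variance 1 over all
twin values; β by default, with a transform switch for M values).
A twin pair is then modeled as bivariate normal with unit variances
and correlation a² + c² (MZ) or a²/2 + c² (DZ), a² + c² + e² = 1.
`fit_ace_ml` maximizes this likelihood directly — it is the same
likelihood a structural-equation model of the classical twin design
maximizes, without an SEM toolchain. Implementation details:

- The likelihood is written on symmetric sufficient statistics
  (Σ(x²+y²), Σxy per zygosity group), so swapping twin labels within
  any pair provably cannot change the fit.
- Optimization: SLSQP over (a², c²) with bounds [0,1] and the
  constraint a² + c² ≤ 1 − 1e-6 (e² stays positive, as it must when
  within-pair variance is nonzero), from the Falconer point plus 3
  seeded Dirichlet starts; tolerance 1e-8 on the log-likelihood.
  Boundary solutions (a² = 0 or c² = 0) are permitted and flagged.
- Non-convergence from every start falls back to the Falconer
  closed-form estimates (truncated at 0, renormalized to sum 1) with
  `converged=False`.
- On data whose sample moments are exact (unit variances, exact group
  correlations), the ML optimum coincides with the Falconer estimates
  at interior points; the test suite uses this as a cross-method
  oracle. At boundary points (e.g. a Falconer c² < 0) the constrained
  ML and the truncate-renormalize closed form legitimately differ.
- No standard errors or confidence intervals are computed; a single
  probe's components at realistic pair counts carry sampling noise of
  a few hundredths (sd ≈ 0.05 per component at 1,000 + 1,000 pairs),
  so recovery checks average over replicate probes.

## Enrichment

Probes are ranked by descending ICC; ties are broken by probe id so
the ranking is deterministic. The enrichment score is the
Subramanian-style weighted Kolmogorov–Smirnov running sum: hits add
|stat|^w normalized over the in-set total (w = 1 by default, the
preranked convention), misses subtract 1/(N − m); ES is the signed
extremum of largest absolute deviation. The null permutes set
membership — random same-size probe sets without replacement — which
is the only null available for published probe lists (no sample-level
data exist). NES divides ES by the mean |null ES| of matching sign;
p-values carry the add-one correction, so the attainable minimum is
1/(n_perm + 1). The permutation engine evaluates the running-sum
extremum from hit positions only (the trajectory is piecewise linear
between hits), vectorized across permutations. All draws come from a
single seeded PCG64 generator.

## Replication tallies

Per probe, over the union of study hit lists: n_consistent =
max(#up, #down), with exact ties labeled `tie`. The published
analyses do not define how a mixed-direction probe is scored; the
majority rule is the default and a strict rule (mixed → 0) is
available via `conflict_rule="zero"`. Probes listed in no study are
excluded from the count-versus-reliability correlation (the universe
is the union of hit lists).

## External associations

Pearson or Spearman correlation of ICC with any per-probe statistic;
concordance bins low (≤ 0.4), mid (0.4, 0.75], high (> 0.75), with
boundary values assigned to the lower bin to match the reliability
category boundaries. Methylation–expression coupling is computed per
TSS link across shared samples (≥ 10 required), with two-sided
p-values from the exact t transform (df = n − 2); zero-variance
probes or units are kept in the output with a flag rather than
silently dropped. TSS assignment is consumed as a link file; no
genome annotation is parsed.

## Subsampling

Draws are without replacement within a draw and independent across
draws (100 by default); each grid point of a sensitivity curve uses
an independent child seed of one master seed. Probes degenerate in a
subsample count as not flagged — conservative for sensitivity.
Specificity is reported alongside sensitivity. Sensitivity of the
identity subsample is exactly 1 by construction.

## Synthetic data: what it emulates, and what it does not

The generator emulates a 350-sample two-platform design on the logit
scale: per probe, true score T ~ N(μ_p, s_p²ρ_p), platform offsets
c_j ~ N(0, σ_c²) fixed per probe-rater, and occasion noise with
variance 2s_p²(1−ρ_p) − σ_c², so the latent-scale ICC(A,2) estimand
is exactly the target ρ_p. Parameter choices:

- **True-ICC mixture** (the study condition): weights
  0.62/0.30/0.08 on Beta(0.5, 8), Beta(1.8, 3.2), Beta(8, 1.5),
  calibrated once against the published summary pattern of 450K–EPIC
  reliabilities — median ≈ 0.09, mean ≈ 0.21, ~6–8% of probes above
  0.75 — with the high component shaped so that probes above 0.75
  concentrate near 0.9, as reported for high cross-tissue-concordance
  probes. Draws are clipped to [0, 0.99]; a true ICC of 1 would
  require noise-free measurement and is excluded.
- **Scale**: the per-measurement logit-scale SD s_p ~ U(0.5, 1.5) is
  held constant across ρ_p (the true-score SD is s_p√ρ_p). This keeps
  low-reliability probes noisy without saturating the inverse-logit;
  parameterizing the true-score SD directly would blow up the noise
  variance as ρ → 0.
- **Platform offset**: σ_c = 0.1 (logit scale), capped at half the
  probe's error budget so every target ρ_p is feasible.
- **Probe means**: μ_p ~ U(−3, 3), covering near-unmethylated through
  near-fully-methylated probes without saturation.

The inverse-logit compresses variance unevenly, so ICCs estimated on
the β scale are mildly attenuated relative to ρ_p (up to ~0.04 for
mid-range ρ at these scales); estimates on logit(β) recover ρ_p
within sampling error. This attenuation is measured and documented
rather than corrected — real β values are similarly bounded.

Twin data: values √a²·A + √c²·C + √e²·E with the classical
correlation structure, plus an optional measurement-error add-on
σ_m² = scale·(1 − ρ_p) that inflates the realized E share of
unreliable probes — reproducing the qualitative coupling in which
reliable probes look heritable and unreliable probes look dominated
by non-shared environment. Only the *sign pattern* of those
couplings is reproducible; the published magnitudes (r ≈ 0.7 with a²,
r ≈ −0.6 with e²) depend on an access-restricted cohort and are not
targets.

Study hit lists: a designated effect-probe subset is detected per
study with probability given by a monotone coupling of true ICC
(constant, linear, or logistic shapes are built in), with a small
direction-flip probability and a false-positive rate for null probes.
Expression: linked units are effect_size·β + Gaussian noise, other
units pure noise.

Not emulated: Infinium I/II probe chemistry, cell-composition
heterogeneity, spatial chip artifacts, batch structure, and
correlated missingness. Passing tests therefore demonstrate correct
statistical behavior under the declared latent model, not robustness
to those artifacts in real arrays.

## Problem sizes used in the checks

Test-suite checks run at reduced but statistically adequate sizes
chosen to keep each check's Monte-Carlo error well inside its
tolerance: recovery grids at 400 probes × 350 samples per point,
twin recovery as the mean over 6 replicate probes at 1,000 + 1,000
pairs, the sign-coupling panel at 2,000 probes (paired n = 100;
150 + 150 twin pairs), enrichment calibration over 500 null sets of
50 probes in a 2,000-probe ranking at 500 permutations, and the
subsampling check at 6,000 probes. The acceptance script runs the
full 20,000 × 350 panel with 100 draws.

## Known limitations

- ICC variants other than ICC(A,k=2) (one-way, consistency,
  single-rating) are out of scope, as are bootstrap CIs.
- The ACE fit assumes bivariate normality of standardized values and
  fits no covariates; ADE and sex-limitation models are out of scope.
- The NES normalization follows the preranked convention stated
  above; published NES values computed under other conventions are
  not directly comparable.
- Whether published twin analyses fed β or M values is not stated in
  the sources this design follows; β is the default here and the
  transform switch makes the alternative one call away.
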