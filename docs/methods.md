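# Methods

Notation: for SNP *j*, γⱼ is the true SNP-exposure effect, Γⱼ the true
SNP-outcome effect, θ the causal effect of exposure X on outcome Y, and dⱼ a
direct (pleiotropic) SNP-outcome effect, so Γⱼ = θγⱼ + dⱼ.

## Harmonization

Outcome records are aligned to the exposure effect allele:

- identical allele pair → kept as is; swapped pair → β and EAF flipped
  (β → −β, f → 1−f);
- palindromic SNPs (A/T, C/G) with exposure EAF inside the ambiguity window
  (default 0.42–0.58) are excluded (`palindromic-ambiguous`); outside the
  window they are oriented by frequency agreement — if
  (f_exp − ½)(f_out − ½) < 0 the outcome record is flipped;
- irreconcilable allele pairs are excluded (`allele-mismatch`).

Exclusions are flagged, never silently dropped; every harmonized set carries
a per-SNP `exclusion_reason`. LD pruning is greedy: order by (p-value, rsid),
keep the best SNP, drop everything with r² ≥ 0.01 against it, repeat. MAF
filtering removes SNPs with min(f, 1−f) < 0.01. Both thresholds are
arguments; the defaults match common MR practice.

## Estimators

All estimators are implemented in closed form (`numpy` linear algebra);
`statsmodels` WLS appears only as an independent oracle in the tests.

- **Wald ratio**: β̂ⱼ = Γ̂ⱼ/γ̂ⱼ, first-order SE σ_{yj}/|γ̂ⱼ|; the
  second-order option adds the Γ̂ⱼ²σ_{xj}²/γ̂ⱼ⁴ delta-method term. SNPs with
  γ̂ⱼ = 0 are dropped with a warning.
- **IVW**: weighted mean of ratios with wⱼ = γ̂ⱼ²/σ_{yj}² (identical to a
  WLS regression of Γ̂ on γ̂ through the origin). Fixed SE = (Σwⱼ)^(−1/2);
  the default *multiplicative random effects* variant scales the SE by
  max(1, √(Q/(k−1))) so heterogeneity widens but never narrows intervals.
  P-values are normal-based.
- **MR-Egger**: WLS of Γ̂ on γ̂ with a free intercept after orienting all
  SNPs to γ̂ⱼ ≥ 0 (the estimator is not invariant to allele orientation, so
  the convention is fixed). SEs are scaled by max(1, √(Q_E/(k−2))) and
  p-values use t(k−2). Requires ≥3 SNPs and non-constant γ̂.
- **Weighted median**: ratios sorted, cumulative midpoint weights
  pⱼ = cumsum(w)ⱼ − wⱼ/2 (weights normalized), linear interpolation at
  probability ½. SE by parametric bootstrap (default 1000 replicates) in
  which γ̂ⱼ and Γ̂ⱼ are re-drawn from their reported SEs. A seed is
  mandatory; replicates are generated in rsid-sorted order so the estimate is
  invariant to input row order.

## Diagnostics

- **Cochran's Q** on the ratio scale with weights γ̂ⱼ²/σ_{yj}², χ²(k−1).
- **Leave-one-SNP-out** IVW for influence analysis.
- **Steiger filtering**: per-SNP variance explained in exposure vs outcome.
  For log-odds betas the default is the latent-logistic scale,
  r² = b²·2f(1−f) / (b²·2f(1−f) + π²/3), which needs no prevalence; for
  linear-scale betas on a binary trait, r² = b²·2f(1−f)/(p(1−p)) (prevalence
  required). The test statistic is the Fisher-z contrast
  z = (atanh√r²_exp − atanh√r²_out)/√(1/(n_exp−3) + 1/(n_out−3)); a SNP is
  removed iff r²_out > r²_exp and the two-sided p < α (default 0.05). α = 0
  is an exact no-op by construction.
- **Instrument strength**: per-SNP F = (β̂/se)², r² = β̂²·2f(1−f)/var(X).

## Cohort-level design

- **One pregnancy per woman**: uniform random choice per woman, seeded.
- **Split cross-over two-sample MR**: the cohort is randomly halved;
  SNP-exposure fits come from one half and SNP-outcome fits from the other,
  in both directions, and the two IVW estimates are pooled by fixed-effects
  meta-analysis. This keeps the two samples non-overlapping when the cohort
  also contributed to the exposure GWAS. The combined estimate equals the
  fixed-effects meta of its two halves as an exact identity (tested on every
  seed). Halves with fewer than `min_cases` (default 10) outcome cases are
  refused rather than fitted unstably.
- **Regression**: logistic fits use IRLS (statsmodels GLM Binomial,
  maxiter 100, tol 1e-8); non-convergence and separation (|β̂| > 15) are
  flagged, never hidden. Per-SNP scans with no covariates use a vectorized
  closed-form univariate OLS that is bit-compatible with the per-SNP path.
- **Tabulation**: printed-table conventions — percentages to one decimal,
  half-up rounding, denominator = column total.

## Meta-analysis

Fixed-effects inverse-variance pooling: β = Σwβᵢ/Σw with w = 1/seᵢ²,
se = (Σw)^(−1/2), between-study Q with m−1 df, and leave-one-study-out. A
single-study "meta" is the identity.

## Synthetic data generator

Genotypes gⱼ ~ Binomial(2, fⱼ), fⱼ ~ U(0.1, 0.5) (configurable).
Instrument effects are heterogeneous — shape multipliers uⱼ ~ U(0.5, 1.5)
rescaled so the instruments jointly explain a target R² (heterogeneity
matters: equal effects make γ̂ constant and MR-Egger collinear).
Binary-liability exposure: X ~ Bernoulli(expit(α_x + Σaⱼgⱼ + c_x U)) with
α_x solved by bisection (tolerance 1e-4) to hit the target prevalence; the
target R² is calibrated on the observed binary scale via the logistic
linearization β_obs ≈ a·p(1−p). Outcome:
Y ~ Bernoulli(expit(α_y + θX + Σdⱼgⱼ + c_y U)) or the analogous linear model
in continuous mode. Fetal genotypes are generated by Mendelian transmission
(one maternal allele + one population allele), giving the expected
maternal-fetal dosage correlation of ½. Pleiotropy regimes: `none`,
`balanced` (dⱼ ~ N(0,σ²)), `directional` (N(μ,σ²)), `proportion-invalid`
(a fraction ρ of SNPs get N(μ,σ²)). A `true_effects()` companion replays the
exact per-SNP truths from the same seed, and a summary-level generator draws
γ̂, Γ̂ directly around their truths for fast estimator calibration.

## Numerical and design choices

- **Continuous mode for recovery**: with a binary exposure and binary outcome
  the MR estimand on the odds-ratio scale is attenuated by non-collapsibility
  and liability-scale mismatch, so exact recovery of θ is not a meaningful
  target there. Recovery tests therefore use continuous exposure and outcome;
  binary mode is validated by calibration (prevalence targets, null
  behaviour) and design identities instead.
- **Recovery conditions** (pre-registered): n = 50,000, 81 SNPs, total
  instrument R² = 10%, θ = 0.3. Weak-instrument theory puts the two-sample
  attenuation near −θ/F̄; at the published instrument strength (R² = 0.42%,
  F̄ ≈ 11) the expected bias ≈ −0.13 would swamp any estimator comparison,
  while at R² = 10% (F̄ ≈ 34 per half-cohort) it is ≈ −0.009, comfortably
  inside the |bias| < 0.02 criterion without being invisible.
- **Published-scale instrument strength**: simulating the exposure GWAS at
  its printed conditions (n = 208,140, 81 SNPs, R² = 0.42%, prevalence 28%)
  yields mean per-SNP F ≈ 11–12, consistent with the noncentral-F mean
  1 + nR²/k ≈ 11.8 and the printed value of 11.
- **Combined-OR round-trips**: the per-source summary estimates behind the
  published combined odds ratios are not redistributable, so the pooling step
  is exercised by decomposing each printed combined estimate (log-OR β, SE
  from the CI width) into two synthetic per-source estimates with distinct
  betas and weights whose fixed-effects pooling recombines exactly to β and
  SE. The decomposition is algebraic, clearly labelled synthetic, and lives
  in `pregmr.published`.
- **Seeds**: every stochastic routine takes an explicit seed; one global seed
  expands into per-stage child seeds via `numpy.random.SeedSequence`
  (reduced mod 2³¹). Pipeline child seeds are keyed on sorted study/outcome
  labels, so results are invariant to configuration order.

## Limitations

- The generator simulates independent SNPs; LD pruning is tested against an
  explicit r² matrix, not simulated haplotypes.
- Binary-outcome MR estimates are marginal log-odds ratios and inherit
  non-collapsibility; they are validated for calibration, not point recovery.
- The synthetic per-source decomposition exercises the pooling arithmetic; it
  does not re-derive the published per-cohort estimates from individual data.
- Steiger r² for binary traits uses the latent-logistic approximation; other
  liability conventions (observed-scale, case-control ascertainment
  corrections) are supported only via the prevalence-based observed-scale
  option.
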