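# pregmr

Two-sample Mendelian randomization (MR) pipeline for estimating the effect of
genetic susceptibility to insomnia on pregnancy and perinatal outcomes
(miscarriage, stillbirth, gestational diabetes, hypertensive disorders of
pregnancy, perinatal depression, preterm birth, and low/high birthweight),
with a synthetic-data layer for validating every estimator against known
truths.

## Scientific problem

Observational associations between insomnia symptoms in pregnancy and adverse
outcomes are confounded. MR sidesteps confounding by using germline genetic
variants as instrumental variables: a SNP that raises insomnia liability is
randomized at conception, so its association with (say) miscarriage can only
run through insomnia — provided the instrument assumptions hold.

The package implements the full analysis:

- **Summary data** — parsing/validation of GWAS summary statistics (TSV),
  allele harmonization with palindromic-SNP handling, greedy LD pruning
  (r² ≥ 0.01 keeps the smallest p-value), and MAF filtering.
- **Estimators** — per-SNP Wald ratios (first- and second-order SEs), IVW
  (fixed and multiplicative random effects), MR-Egger (slope + pleiotropy
  intercept), and the bootstrap-SE weighted median. All closed-form, with
  `statsmodels` used only as an independent test oracle.
- **Diagnostics** — Cochran's Q, leave-one-SNP-out, Steiger directionality
  filtering (latent-scale r² for binary traits), per-SNP F-statistics and
  variance explained.
- **Cohort models** — one-pregnancy-per-woman selection, per-SNP
  linear/logistic association fits (vectorized for GWAS-scale scans), split
  cross-over two-sample MR inside a single cohort, fetal-genotype adjustment,
  and crude/adjusted multivariable logistic regression with printed-table
  style tabulation (half-up rounding to one decimal).
- **Meta pipeline** — fixed-effects inverse-variance pooling across studies,
  between-study Q, leave-one-study-out, and a YAML-driven multi-study,
  multi-outcome runner (`pregmr pipeline`).
- **Synthetic data** — a seeded generator for genotypes, binary-liability or
  continuous exposures, binary or continuous outcomes, confounding,
  fetal-genotype transmission, and four horizontal-pleiotropy regimes
  (none / balanced / directional / proportion-invalid).

## Model

For SNP *j*, let γ̂ⱼ (SE σ_{xj}) be its exposure association and Γ̂ⱼ
(SE σ_{yj}) its outcome association from non-overlapping samples. The Wald
ratio is β̂ⱼ = Γ̂ⱼ/γ̂ⱼ. IVW pools ratios with weights wⱼ = γ̂ⱼ²/σ_{yj}²,
equivalently a weighted regression of Γ̂ on γ̂ through the origin:

    β̂_IVW = Σ wⱼ β̂ⱼ / Σ wⱼ ,   se_fixed = (Σ wⱼ)^(-1/2)

The multiplicative random-effects variant inflates the SE by
max(1, √(Q/(k−1))) where Q is Cochran's Q. MR-Egger frees the intercept
(average directional pleiotropy); the weighted median takes the
weight-interpolated 50% quantile of the ratios and is consistent while <50%
of the weight comes from invalid instruments. Binary outcomes are analyzed
on the log-odds scale, so exp(β̂) is an odds ratio per unit liability.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
cohorts (step 1 writes regenerable cohort data to `scratch/`, all result
tables go to `results/`):

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_instrument_strength.py
python analysis/03_split_crossover_mr.py
python analysis/04_two_sample_mr.py
python analysis/05_meta_analysis.py
python analysis/06_multivariable_regression.py
```

Step 5, for example, pools the per-study IVW estimates and round-trips the
published combined odds ratios through a synthetic per-source decomposition:

```
synthetic outcome, combined IVW OR 1.692 (95% CI 1.167, 2.453)
gestational_diabetes: printed OR 1.20 -> recombined 1.20
low_birthweight: printed OR 3.17 -> recombined 3.17
miscarriage: printed OR 1.60 -> recombined 1.60
perinatal_depression: printed OR 3.56 -> recombined 3.56
```

The same workflow is available as a CLI (`pregmr simulate | harmonize | mr |
diagnose | meta | regress | pipeline`); every subcommand writes its outputs
plus a `manifest.json` recording version, parameters, seeds and input
digests.

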