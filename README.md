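# mrtriad

Three-step two-sample Mendelian randomization (MR) with mediation, built
for GWAS summary statistics: screen many exposures against an outcome,
exclude reverse-causal hits, screen candidate mediators, and decompose each
surviving exposure's effect into direct and mediated components by the
product of coefficients.

## What it does

1. **Instrument selection & harmonization** (`mrtriad.instruments`) —
   p-value thresholding (default `p < 1e-5`), greedy LD clumping
   (r² < 0.001 within 10,000 kb, with an optional pairwise-r² matrix;
   distance-only degradation without one), per-SNP strength filter
   `F = (beta/se)² >= 10`, and exposure–outcome allele harmonization with
   frequency-based resolution of palindromic variants.
2. **Five estimators** (`mrtriad.estimators`) — multiplicative
   random-effects IVW (identical to zero-intercept weighted least squares),
   Egger regression with intercept test, weighted median, and simple /
   weighted mode with kernel-density argmax and parametric-bootstrap
   standard errors. `to_odds_ratio` converts log-odds effects to
   `OR = exp(beta)` with `exp(beta ± 1.96·se)` bounds.
3. **Sensitivity diagnostics** (`mrtriad.sensitivity`) — Cochran's Q,
   Egger intercept, a seeded simulation-based outlier procedure
   (global / per-SNP / distortion tests), and leave-one-out influence.
4. **Mediation** (`mrtriad.mediation`) — indirect effect `beta1 × beta2`
   with delta-method (or Sobel / bootstrap) intervals, direct effect,
   and the mediated proportion `indirect / total` (reported negative and
   flagged when the paths oppose — never clamped).
5. **Synthetic data** (`mrtriad.synthetic`) — a seeded generator of
   exposure / mediator / outcome summary statistics with configurable
   causal effects, directional pleiotropy, LD blocks, and analytic GWAS
   standard errors, plus the serialized ground truth.
6. **Pipeline & CLI** (`mrtriad.pipeline`, `mrtriad.cli`) — the three-step
   screen end-to-end, writing per-stage TSVs and a JSON run manifest.

## CLI

```bash
# write a simulated triple (exposure.tsv, mediator.tsv, outcome.tsv, truth.json)
mrtriad simulate --seed 7 --outdir sim/

# forward screen of exposures on the outcome
mrtriad screen --exposure sim/exposure.tsv --outcome sim/outcome.tsv --out screen.tsv

# reverse MR (outcome instruments against each target)
mrtriad reverse --outcome sim/outcome.tsv --target sim/exposure.tsv --out reverse.tsv

# full three-step run
mrtriad run-all --exposure sim/exposure.tsv --mediator sim/mediator.tsv \
    --outcome sim/outcome.tsv --outdir results/
```

Input files are tab-separated (gzip-transparent) with canonical columns
`snp_id chrom pos effect_allele other_allele eaf beta se pval n`; other
dialects map through `--config` / `column_map`. Thresholds, alphas, seeds
and bootstrap sizes are configurable through a JSON config file and are
echoed into every run manifest.

## Notes on conventions

- F-statistic is the standard per-SNP approximation `(beta/se)²`.
- IVW weights are inverse variances `1/se²`; random-effects variance
  inflation is floored at 1 (a fixed-effects switch exists).
- Egger p-values use a t distribution with J−2 df; confidence intervals use
  a fixed z of 1.96 throughout for consistency with the OR formula above.
- Harmonized rows are re-oriented to non-negative exposure betas by default
  (required for a sign-consistent Egger intercept).
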