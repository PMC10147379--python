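# tsmr

A two-sample Mendelian randomization (MR) toolkit built around GWAS
summary statistics:

- **sumstats** — read/validate/write delimited summary-statistics tables
  with a configurable column map and per-row audit of dropped records.
- **instruments** — genome-wide significance filtering (p < 5e-8 by
  default), greedy LD clumping against a user-supplied r² matrix
  (r² < 0.001, 10 Mb window by default), per-SNP F statistics, instrument
  R², and the overall F statistic.
- **harmonize** — merge exposure and outcome records onto the exposure's
  effect-allele orientation, resolving allele swaps and strand flips;
  palindromic SNPs are kept only when both minor-allele frequencies are
  below 0.3 and their orientation can be inferred from frequency.
- **estimators** — per-SNP Wald ratios; IVW (multiplicative random
  effects by default), MR-Egger (slope + pleiotropy intercept), weighted
  median and weighted mode with seeded parametric-bootstrap SEs; the
  I²(GX) measurement-error diagnostic and SIMEX-corrected Egger.
- **diagnostics** — Cochran Q (IVW and Egger variants) and a
  residual-sum outlier analysis (global test, per-SNP outliers,
  distortion test, outlier-corrected IVW).
- **power** — analytic power and minimal-detectable odds ratio for a
  case-control outcome.
- **simulate** — seeded generator of two-sample summary statistics with
  known causal truth: configurable pleiotropy regimes (balanced /
  directional / InSIDE-violating), planted outliers, palindromic alleles,
  block LD, and named scenario presets.
- **pipeline / CLI** — orchestrates the full battery per
  exposure × outcome pair with the conditional gates (SIMEX when
  I²(GX) < 0.90, outlier analysis when Q p < 0.05) and writes
  estimate/diagnostic/audit/scatter reports.

## CLI

```bash
# synthetic dataset with known truth
tsmr simulate --preset directional --seed 7 -o sim/

# full analysis from a config file
tsmr run -c analysis.yaml -o results/

# power grid
tsmr power --n-total 12619 --case-fraction 0.478 --r2 0.04
```

A minimal `analysis.yaml`:

```yaml
exposure:
  path: sim/exposure.tsv
  name: exposure
  trait_type: continuous
  # column_map: {snp_id: SNP, effect_allele: EA, ...}   # if headers differ
outcomes:
  - path: sim/outcome.tsv
    name: disease
    trait_type: binary        # estimates exported as OR (95% CI)
ld:
  path: sim/ld.tsv
  format: square              # or "long" (snp_a, snp_b, r2)
settings:
  p_select: 5.0e-8
  clump_r2: 0.001
  palindrome_maf: 0.3
  n_boot: 1000
  seed: 0
```

Outputs under `results/`: `estimates.tsv`, `diagnostics.tsv`,
`table1.tsv` (OR (95% CI) + p per method), `audit.json`, and one
`scatter_<exposure>_<outcome>.tsv` per analysis with the per-SNP effects.

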