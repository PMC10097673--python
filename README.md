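# micromr

Two-sample Mendelian randomization (MR) toolkit for microbiome-style
exposures on binary disease outcomes, built around plain-text GWAS summary
statistics. It covers the full design of a summary-level MR study:

- **`micromr.sumstats`** — read/write/validate summary-statistics TSVs with a
  configurable column map; harmonize exposure/outcome pairs to a shared
  effect allele (strand flips, palindromic A/T–G/C resolution from allele
  frequency, MAF > 0.42 ambiguity removal).
- **`micromr.instruments`** — p-value threshold selection, inverse-variance
  fixed-effects meta-analysis across cohorts with a "meta-supported" rule,
  lenient-threshold + cross-cohort directional-consistency filtering, greedy
  LD clumping, variance explained (observed and liability scale),
  F-statistics, and asymptotic power for a binary-outcome MR design.
- **`micromr.estimators`** — Wald ratio, fixed-effects IVW, MR-Egger (with
  the intercept test for directional pleiotropy), weighted median, weighted
  mode, Cochran's Q, leave-one-out, and odds-ratio scaling (including the
  ln 2 "per doubling of liability" scale for presence/absence exposures).
- **`micromr.coloc`** — approximate-Bayes-factor colocalisation enumerating
  posterior probabilities of H0–H4 for a region pair, with log-space
  accumulation and a ≥ 0.80 H4 colocalisation call.
- **`micromr.screen`** — offline pleiotropy screening of instrument variants
  against a local association-catalogue TSV at a lenient (fractional
  Bonferroni) threshold, with per-trait-class hit counts.
- **`micromr.simulate`** — synthetic cohorts with LD-blocked genotypes,
  hurdle microbial traits (presence/absence + rank-normalized abundance),
  case-control outcomes, per-cohort association scans, regional datasets for
  colocalisation, catalogue fixtures, and a fast closed-form summary backend
  — all seeded and deterministic with known ground truth.
- **`micromr.pipeline` / `micromr.cli`** — config-driven orchestration of
  forward MR per trait per outcome site, the sensitivity battery
  (colocalisation, screening, lenient multi-estimator analysis) and
  reverse-direction MR, with TSV tables and a JSON manifest.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle equivalence
of every estimator against independent implementations, colocalisation
scenario recovery over 100 seeded regions each, 500-replicate parameter
recovery, 2000-replicate type-I error, reverse-direction sanity, and the
harmonization contract).

## CLI

All verbs read a YAML config; `--seed`/`--outdir` override config keys.

```bash
micromr simulate  --config config.yaml          # synthetic scenario data
micromr harmonize --exposure exp.tsv --outcome out.tsv --out pairs.tsv
micromr mr        --config config.yaml          # forward MR per trait x site
micromr coloc     --config config.yaml          # coloc for flagged traits
micromr screen    --config config.yaml          # catalogue pleiotropy screen
micromr reverse   --config config.yaml          # disease -> trait MR
micromr all       --config config.yaml          # everything + manifest
```

Minimal config:

```yaml
seed: 1
outdir: out
exposures:
  - trait_id: g_example
    measure: AB            # or PA (then also: prevalence: 0.6)
    sumstats: exposure.tsv
    threshold: 2.5e-8
outcomes:
  - site: overall          # overall/distal/proximal/colon/rectal
    sumstats: outcome.tsv
sensitivity:
  screen: true
  catalogue: catalogue.tsv
reverse:
  sumstats: disease.tsv
  ld: ld.tsv
  threshold: 5.0e-8
  clump_r2: 0.001
```

## File formats

Summary statistics are tab-delimited with a header
(`variant_id, chromosome, position, effect_allele, other_allele, eaf, beta,
se, pvalue, n, ...`); arbitrary layouts are supported through a column map.
Harmonized pairs, catalogue files, screen reports, result tables and LD
matrices (whitespace-delimited, variant-id header row) are likewise plain
text.
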