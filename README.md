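# drmatch

Donor-recipient (D-R) genetic mismatch analysis for kidney-transplant
cohorts.

In transplantation, the graft exposes the recipient's immune system to
every donor allele the recipient does not carry.  Beyond HLA, these
non-HLA mismatches — most of them in introns and other non-coding
sequence — associate with long-term, death-censored graft loss (DCGL).
`drmatch` implements the full analysis for paired donor/recipient SNP
data:

* **variant-level mismatch calls** — at a biallelic variant, the donor
  introduces `n` "alien" allele copies, with `n = g_D` when the recipient
  is homozygous reference, `n = 2 − g_D` when homozygous alternate, and
  `n = 0` for a heterozygous recipient (single / double / any mismatch);
* **gene-level and genome-wide scores** — sums of 0/1 mismatch indicators
  over gene bodies or the whole genome (MHC excluded), normalized by the
  cohort interquartile range: `S_norm = S_raw / IQR(S_raw)`;
* **survival screens** — Cox proportional-hazards models
  (`h(t|x) = h₀(t)·exp(βᵀx)`, Efron ties, Newton-Raphson) testing each
  gene or locus variant across four scenarios (any/double mismatch ×
  full cohort / ancestry-homogeneous subset), with Kaplan-Meier curves and
  log-rank tests;
* **haplotype blocks** — sets of variants in near-perfect LD
  (pairwise r² > 0.99 by EM from unphased genotypes) treated as one
  biallelic locus, with per-sample minor-haplotype dosage, per-pair
  mismatch dosage, and directionality classes (minor-into-major vs
  major-into-minor vs the tag-SNP risk mismatch: risk allele introduced
  into a recipient homozygous for the non-risk allele);
* **expression support** — additive cis-eQTL tests of dosage against
  log2(TPM+1) expression and seed-gene coexpression (|r| ≥ 0.6,
  Benjamini-Hochberg adjusted p ≤ 0.05);
* **a synthetic cohort generator** — ancestry-structured allele
  frequencies (Balding-Nichols), kinship, a planted LD block and tag SNP,
  mismatch-dependent survival and genotype-dependent expression, with the
  ground truth retained so every pipeline estimate is checked in closed
  loop.

It is written for genetic-epidemiology and transplant-genomics analysts
working with imputed VCF genotypes, a D-R pairing table with clinical
covariates (TSV), gene annotation (BED) and a variant functional-class
table.

## Worked example

```python
import pandas as pd
from drmatch import (CohortConfig, simulate_cohort, build_mismatch_table,
                     genome_wide_score, fit_cox, build_block, haplotype_dosage)
from drmatch.genotype_io import mhc_region

cohort = simulate_cohort(CohortConfig(seed=7))   # 385 pairs, 20,000 variants
table = build_mismatch_table(cohort.matrix, cohort.cohort)
score = genome_wide_score(table, exclude=mhc_region())
print("raw score, first 3 pairs:", score.raw[:3], " IQR:", round(score.iqr, 1))

t = cohort.cohort.table
fit = fit_cox(t["follow_time"], t["event"],
              pd.DataFrame({"score": score.normalized}))
row = fit.summary.loc["score"]
print(f"genome-wide mismatch HR {row['hr']:.2f} "
      f"(95% CI {row['ci_lower']:.2f}-{row['ci_upper']:.2f}, p={row['p']:.3g}, "
      f"{fit.n_events} events)")

block = build_block(cohort.matrix, cohort.truth.block_member_ids,
                    r2_in=0.99, tag_variant="tag_snp", r2_out=0.5)
dosage, discordance = haplotype_dosage(block, cohort.matrix)
print(f"block of {len(block)} SNPs, minor-haplotype frequency {block.minor_hap_freq:.3f}")
```

prints

```
raw score, first 3 pairs: [6109 4260 4222]  IQR: 1750.0
genome-wide mismatch HR 1.50 (95% CI 0.86-2.61, p=0.154, 57 events)
block of 30 SNPs, minor-haplotype frequency 0.331
```

Each pair's raw score counts its mismatched variants (here thousands,
driven by ancestry and kinship); dividing by the cohort IQR puts cohorts
genotyped on different platforms on one scale.  The hazard ratio of 1.50
per normalized-score unit is the estimated DCGL risk increase — with only
57 events a single cohort of this size carries a wide confidence interval,
which is why the screening layer intersects several scenarios.  The block
recovered all 30 planted SNPs as one haplotype whose minor allele runs at
33% in this mixed-ancestry cohort.

## Command-line pipeline

```sh
drmatch all --config pipeline.yaml --out results/
```

runs simulate → qc → mismatch → screen → haplotype → eqtl; each stage can
also be run alone and writes its resolved configuration next to its
outputs.  Outputs are byte-deterministic for a fixed configuration and
seed.

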