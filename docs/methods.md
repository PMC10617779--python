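# Methods

`drmatch` quantifies genetic incompatibility between a kidney donor and
recipient outside the HLA region and screens it for association with
death-censored graft loss (DCGL).  This note documents the models, the
conventions and defaults, what the synthetic cohort generator does and does
not emulate, and the numerical choices a maintainer would want to know.

## Mismatch model

At a biallelic variant with donor genotype `g_D` and recipient genotype
`g_R` (ALT-allele counts in {0, 1, 2}), a **mismatch** occurs when the
donor carries an allele absent from the recipient.  The number of "alien"
allele copies the donor would introduce is

    n(g_D, g_R) = g_D        if g_R = 0
                = 2 - g_D    if g_R = 2
                = 0          if g_R = 1   (a heterozygous recipient carries
                                           both alleles)

giving a *single* (n = 1) or *double* (n = 2) mismatch; *any* mismatch is
n >= 1.  The relation is deliberately asymmetric: it models what the graft
exposes to the recipient's immune system, not genetic distance.

Scores at coarser scales sum the 0/1 presence indicator of the chosen
mismatch class over a variant set:

* **gene-level** — all QC-passing variants inside the annotated gene body
  (introns included: the motivating candidate variants are intronic), after
  removing variants whose cohort mismatch frequency is below 5% so that
  near-private mismatches cannot drive a gene signal;
* **genome-wide** — all QC-passing variants outside the extended MHC
  interval (chr6:28,866,528-33,775,446, hg19, 1-based inclusive), *without*
  the 5% mismatch-frequency filter;
* **region-class** — the same restricted to exonic / non-exonic /
  transmembrane-nonsynonymous variants.

Raw scores are normalized by the cohort interquartile range of the raw
scores (`S_norm = S_raw / IQR`), which makes the score comparable across
genotyping platforms and imputation densities.  Quantiles use linear
interpolation (numpy's default); the convention is configurable and logged
because published IQR normalizations rarely state it.  Gene-level screens
use raw counts as the exposure: per-gene IQRs are frequently zero and the
per-unit hazard ratio is then directly interpretable.

Missing genotype calls propagate to a missing mismatch call and are
excluded from sums without rescaling (optional per-pair rescaling by
`n_total / n_nonmissing` exists but is off by default).

## Quality control

Variant filters apply in a fixed order, each variant charged to the first
filter it fails, so reports reconcile exactly: imputation INFO < 0.4 →
missing rate > 0.05 → monomorphic → MAF < 0.01 → Hardy-Weinberg exact
p < 1e-6 → MHC interval.  Genotype posteriors below 0.95 are masked to
missing at VCF read time.  The HWE exact test is the conditional
enumeration over heterozygote counts (sum of probabilities of
configurations no more probable than the observed one); it is tested
against an exact-rational enumeration for every configuration with n <= 50.
HWE is computed across all samples by default, with an option to restrict
(e.g. to recipients plus living donors) since pooling related genomes can
distort the test; the appropriate sample set is a judgement call we leave
to the analyst.

Multiallelic records are rejected rather than decomposed: the mismatch
definition is stated on allele presence and no decomposition rule would be
principled.

## Kinship

Pairwise relatedness (pihat = P(IBD=1)/2 + P(IBD=2)) uses the
genomic-relationship moment estimator
`mean[(g_i - 2p)(g_j - 2p) / (2 p (1 - p))]` over pairwise-complete
variants with MAF >= 0.05, truncated to [0, 1].  With allele frequencies
matched to the pair's population it is unbiased (self ~ 1,
parent-offspring ~ 0.5, unrelated ~ 0); with pooled frequencies in a
structured cohort it inherits the usual upward bias for same-ancestry
pairs, which is why the genome-wide mismatch score (not pihat) is the
primary quantification.

## Haplotype block and directionality

A **block** is a set of variants in near-perfect LD treated as one
biallelic locus (minor vs major haplotype).  Two-locus r² is estimated
from unphased genotypes by EM over the double-heterozygote phase ambiguity
(converged at max frequency change < 1e-10 or 1000 iterations);
r² = D²/(pA qA pB qB).  Block construction greedily removes the
lowest-connectivity candidate until all pairwise r² >= 0.99 (connectivity
ties resolved by genomic position, earliest kept), then verifies every
member has r² < 0.5 with the designated tag SNP.  Minor/major orientation
is cohort-relative: each member's allele is phased onto the haplotype
anchored at the first member's rarer allele via the sign of D, and the
orientation flips if that haplotype's frequency reaches 0.5 (exact ties
resolve toward the ALT-bearing haplotype).

Because genotypes are unphased, per-sample **haplotype dosage** is the
minor-allele count supported by a strict majority of non-missing members;
a tie or more than half the members missing yields a missing dosage, and
the per-sample discordance rate (fraction of members outvoted) is
reported.  In the near-perfect LD regime the vote is almost always
unanimous; the rule only matters for recombinants and genotyping error.

Per-pair haplotype mismatch applies the variant-level containment rule to
the dosages, and each pair gets exactly one **direction class**:

1. `TAG_RISK` — tag-SNP risk mismatch (recipient homozygous for the
   non-risk allele, donor carrying >= 1 risk allele), taking precedence
   regardless of haplotype status.  This precedence changes group sizes
   and is deliberate: it isolates the previously reported tag-SNP effect
   from the new haplotype effect.
2. `MINOR_INTRODUCING` — donor introduces the minor haplotype allele into
   a homozygous-major recipient.
3. `MAJOR_INTRODUCING` — the converse.
4. `OTHER` — no qualifying mismatch.

## Survival association

The Cox proportional-hazards fitter maximizes the partial likelihood by
Newton-Raphson with step halving (Efron tie handling by default, Breslow
by flag, optional strata), declaring convergence when the largest score
component is below 1e-8 within 50 iterations.  Non-convergence, singular
information, and extreme coefficients (|beta| > 15, i.e. monotone
likelihood / separation) are flagged on the fit, never silent.  The fitter
is implemented in-package because the screens refit the same small model
thousands of times; it is cross-checked in the tests against lifelines
(coefficients and standard errors to ~1e-6) and against a grid-search
maximization of the written-out partial likelihood on micro-data, and the
two-group log-rank statistic is verified to equal the Cox score test at
beta = 0.

Screens follow the cohort-study design: each gene's mismatch count is
tested one gene at a time, adjusting the normalized genome-wide score, HLA
mismatch score, induction therapy and donor status, under four scenarios
(any/double mismatch x full cohort / ancestry-homogeneous subset); a unit
is flagged when nominally significant (default p <= 0.05) in every
scenario.  There is **no multiplicity correction at the screen stage** —
the intersection across scenarios (plus external validation) plays the
role of error control in this screening design, and is documented as a
design choice rather than best practice.  Variant-level locus screens test each
variant's any-mismatch indicator (a) adjusted by the tag-risk indicator
and (b) within the tag-non-risk stratum, in the full cohort and the
subset.  Pairs with missing covariates are dropped listwise.

## Expression side

eQTL tests are ordinary least squares of log2(TPM+1) expression on allele
(or haplotype) dosage plus age, sex and ancestry, with an ordinary t-test
on the dosage coefficient.  No empirical-Bayes variance moderation is
applied: at the emulated cohort size (~90-385 samples) moderated and
ordinary t differ negligibly, and the ordinary test keeps the
transcriptome-wide scan a closed-form residualization (Frisch-Waugh),
which is exactly equal to the per-gene fit.  Transcriptome-wide p-values
are Benjamini-Hochberg adjusted.  Coexpression is Pearson correlation
against a seed gene with BH adjustment over all tested genes; the
coexpressed set requires |r| >= 0.6 and adjusted p <= 0.05 (both
thresholds configurable, with an optional positive-only restriction).

## Synthetic cohort generator

The generator emulates the *structure* of a transplant genotype study so
every estimate the pipeline produces can be checked against a planted
truth.  Defaults are the study conditions: 385 pairs, 13% target event
rate, 1,824-day administrative horizon, a 30-SNP block, three ancestries
(EUR/AFR/EAS at 0.60/0.25/0.15) at divergence F = 0.1, relatedness mix
70/20/10 at expected IBD 0/0.25/0.5, ancestry-specific minor-haplotype
frequencies 0.37/0.097/0.62 and tag-risk-allele frequencies
0.568/0.75/0.98 (the span reported across reference populations for the
motivating locus).

* **Frequencies** — Balding-Nichols: ancestral p0 ~ U(0.05, 0.95),
  per-ancestry Beta(p0(1-F)/F, (1-p0)(1-F)/F).
* **Kinship** — locus-independent copying: one donor haplotype copies the
  matched recipient haplotype at each background locus independently with
  probability 2f.  This reproduces pihat and score structure exactly but
  produces no IBD segments and no genome-wide LD decay; LD exists only
  inside the constructed block.  Passing tests therefore say nothing about
  segment-based IBD estimators or LD pruning on real data.
* **Block and tag** — intact two-state haplotypes (within-block r² ~ 1,
  optional recombinant fraction); the tag SNP and its optional high-LD
  partners (target r² set by a per-haplotype redraw probability
  1 - sqrt(r²)) are drawn independently of the block pool.
* **Survival** — exponential event times with rate
  `lam0 * exp(b_gw S_norm + b_minor 1[minor] + b_tag 1[tag-risk] +
  b_gene * gene alien count)`, censoring `C = min(horizon, U(0, 2 horizon))`,
  and `lam0` calibrated by bisection on the closed-form expected event
  rate given the realized linear predictors (exact in expectation; the
  realized rate carries binomial noise, +/- 1.7 percentage points at
  n = 385).  The exponential baseline satisfies proportional hazards
  exactly, so Cox recovery tests are not biased by model misspecification.
  Default hazard ratios: 1.46 per normalized genome-wide unit, 2.0 for
  minor-introducing, 1.8 for tag-risk.
* **Causal gene** — when planted, its variants are drawn as an intact
  haplotype cluster (the way the motivating locus behaves) and its hazard
  scales per introduced allele *copy* — a dosage model, so single and
  double mismatches carry one and two log-hazard units per variant and the
  any- and double-mismatch screens share one underlying signal.
* **Expression** — target gene = baseline + effect x dosage + small
  age/sex effects + Gaussian noise (clipped at 0), pure-noise genes, and
  an optional planted coexpression module at a chosen true correlation
  with the target.

All randomness flows from a single `numpy` Generator seeded once; emitted
files are byte-deterministic given config and seed.

## Problem sizes in the validation suite

Closed-loop checks run at desk scale chosen to make each estimate's
sampling error small relative to its tolerance: 20,000 variants for
kinship and score-structure checks, n = 400 pairs and 200-1,000 replicates
for Cox calibration, 20 seeded replicates for screen and directionality
recovery, and 500 replicates for FDR control.  The acceptance script runs
the full pipeline once at the emulated study scale (385 pairs, 20,000
variants, 250 genes) plus a 501-gene screen cohort.

## Known limitations

* No segment-based IBD, LD decay, or coalescent realism; ancestry labels
  are categorical inputs, never inferred.
* The screens' intersection-of-nominal-p design is not a calibrated
  multiple-testing procedure; treat flagged units as candidates for
  validation, not discoveries.
* Directional survival contrasts at the default event rate (13%, ~50
  events per 400 pairs) have limited log-rank power (~55-65% at HR 2 for a
  20% group); detecting directionality reliably needs larger effect sizes
  or event counts than the default conditions provide.
* The rank correlation between mismatch score and true IBD fraction is
  bounded away from -1 by construction when 70% of pairs sit at exactly
  IBD 0 (tied ranks cap |rho| near 0.8; the linear correlation is
  typically below -0.9).
* Haplotype dosage by majority vote assumes near-perfect LD; it degrades
  gracefully (missing dosage, reported discordance) but is not a
  statistical phaser.
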