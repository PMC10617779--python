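"""Synthetic transplant-cohort generator with retained ground truth.

Generates complete, self-consistent pipeline inputs — paired donor and
recipient genotypes with ancestry structure and kinship, a planted
near-perfect-LD causal haplotype plus an unlinked tag SNP, survival
outcomes driven by a proportional-hazards model on the realized mismatch
scores, and genotype-dependent expression for one cis-regulated gene — so
that every stage of the analysis can be exercised and every generator
parameter the pipeline estimates can be checked in closed loop.

Model choices (and their limits):

* Allele frequencies follow the Balding-Nichols model: an ancestral
  frequency ``p0 ~ Uniform(0.05, 0.95)`` per variant and per-ancestry
  frequencies ``Beta(p0 (1-F)/F, (1-p0)(1-F)/F)`` with divergence ``F``.
* Kinship uses a locus-independent IBD model: for a pair with expected IBD
  fraction ``f`` (pihat), each background locus of one donor haplotype is
  copied from the matched recipient haplotype independently with
  probability ``2 f``.  This reproduces pihat and mismatch-score structure
  but not segment lengths or genome-wide LD decay; LD exists only inside
  the constructed block.
* The haplotype block is drawn as intact two-state haplotypes (minor vs
  major), giving within-block r-squared ~ 1; the tag SNP is drawn
  independently of the block conditional on its ancestry-specific
  frequency, giving r-squared well below 0.5.
* Event times are exponential with rate
  ``lam0 * exp(b_gw * S_norm + b_minor * 1[minor-introducing] + b_tag *
  1[tag-risk] + b_gene * gene_score)``; ``lam0`` is calibrated by bisection
  so the expected event rate matches the target (13% by default) given the
  censoring scheme ``C = min(horizon, Uniform(0, 2 * horizon))``.

Default parameters define the study conditions this generator emulates
(385 pairs, 13% event rate, 1,824-day horizon, a 30-SNP block, ancestry-
dependent minor-haplotype and tag-risk-allele frequencies) without claiming
to reproduce any real-data result.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genotype_io, mismatch as mm
from .eqtl import ExpressionMatrix
from .genotype_io import MISSING, GenotypeMatrix, PairCohort, RegionAnnotation, ValidationError
from .haplotype import classify_directions

logger = logging.getLogger(__name__)

LOG = np.log


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class AncestrySpec:
    """Ancestry labels, cohort proportions, and Balding-Nichols divergence F."""

    labels: tuple[str, ...] = ("EUR", "AFR", "EAS")
    proportions: tuple[float, ...] = (0.6, 0.25, 0.15)
    fst: float = 0.1

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.proportions):
            raise ValidationError("ancestry labels and proportions must align")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValidationError("ancestry proportions must sum to 1")
        if not 0.0 <= self.fst < 1.0:
            raise ValidationError("fst must be in [0, 1)")


@dataclass
class RelatednessSpec:
    """Mix of pairs at expected IBD fraction 0 / 0.25 / 0.5.

    Related classes model living-related donors (same ancestry as the
    recipient); unrelated pairs are deceased-donor with probability
    ``1 - living_unrelated_fraction``.
    """

    proportions: tuple[float, float, float] = (0.7, 0.2, 0.1)
    ibd_fractions: tuple[float, float, float] = (0.0, 0.25, 0.5)
    living_unrelated_fraction: float = 0.3

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValidationError("relatedness proportions must sum to 1")


@dataclass
class BlockSpec:
    """The planted causal haplotype: n SNPs in near-perfect LD."""

    n_snps: int = 30
    minor_hap_freq: dict[str, float] = field(
        default_factory=lambda: {"EUR": 0.37, "AFR": 0.097, "EAS": 0.62}
    )
    recombinant_fraction: float = 0.0
    chrom: str = "chr2"
    start_pos: int = 109_200_000
    spacing: int = 1_000


@dataclass
class TagSpec:
    """The tag SNP (rs893403-like): risk allele = ALT, unlinked to the block."""

    risk_allele_freq: dict[str, float] = field(
        default_factory=lambda: {"EUR": 0.568, "AFR": 0.75, "EAS": 0.98}
    )
    #: optional partners in high LD with the tag (regulatory-candidate
    #: mimics); each entry is the target r-squared to the tag
    partner_r2: tuple[float, ...] = ()


@dataclass
class HazardSpec:
    """Proportional-hazards generative model for graft-loss times."""

    beta_genome_wide: float = LOG(1.46)  # per normalized-score unit
    beta_minor_introducing: float = LOG(2.0)
    beta_tag_risk: float = LOG(1.8)
    beta_gene: float = 0.0  # per raw mismatch unit at `causal_gene`
    causal_gene: str | None = None
    #: draw the causal gene's variants as intact two-state haplotypes (the
    #: way the real candidate locus behaves: an intronic LD cluster), so the
    #: any- and double-mismatch gene scores share one underlying mismatch
    causal_gene_ld: bool = True
    causal_gene_minor_freq: float = 0.35
    event_rate: float = 0.13
    horizon_days: float = 1824.0

    def __post_init__(self) -> None:
        if not 0.0 < self.event_rate < 1.0:
            raise ValidationError("event_rate must be in (0, 1)")
        if self.horizon_days < 0:
            raise ValidationError("horizon_days must be >= 0")


@dataclass
class EqtlSpec:
    """Additive cis-eQTL for one target gene plus noise genes."""

    effect: float = 0.5  # expression units per minor-haplotype allele
    noise_sd: float = 1.0
    n_genes: int = 1000
    target_gene: str = "eqtl_target"
    module_size: int = 0  # planted coexpression module around the target
    module_r: float = 0.8
    age_effect: float = 0.005
    sex_effect: float = 0.1
    baseline: float = 4.0


@dataclass
class CohortConfig:
    """All study conditions for one synthetic cohort; one seed, no hidden entropy."""

    n_pairs: int = 385
    n_variants: int = 20_000  # background biallelic variants on chr1
    n_genes: int = 200
    variants_per_gene: int = 5
    n_mhc_decoys: int = 5  # variants inside the MHC interval (removed by QC)
    n_low_info: int = 5  # variants flagged with low imputation INFO score
    missing_rate: float = 0.002
    ancestry: AncestrySpec = field(default_factory=AncestrySpec)
    relatedness: RelatednessSpec = field(default_factory=RelatednessSpec)
    block: BlockSpec = field(default_factory=BlockSpec)
    tag: TagSpec = field(default_factory=TagSpec)
    hazard: HazardSpec = field(default_factory=HazardSpec)
    eqtl: EqtlSpec = field(default_factory=EqtlSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes * self.variants_per_gene > self.n_variants:
            raise ValidationError("n_genes * variants_per_gene exceeds n_variants")
        for label in self.ancestry.labels:
            if label not in self.block.minor_hap_freq:
                raise ValidationError(f"block minor_hap_freq missing ancestry {label!r}")
            if label not in self.tag.risk_allele_freq:
                raise ValidationError(f"tag risk_allele_freq missing ancestry {label!r}")


@dataclass
class TruthRecord:
    """Ground truth retained for closed-loop recovery tests."""

    pairs: pd.DataFrame  # true_ibd, dosages, tag genotypes, direction class, eta
    variants: pd.DataFrame  # variant_id, role, gene_id, variant_class
    block_member_ids: list[str]
    tag_id: str
    betas: dict[str, float]
    genome_score_raw: np.ndarray
    genome_score_normalized: np.ndarray
    lambda0: float


@dataclass
class SyntheticCohort:
    """A complete in-memory cohort: inputs plus ground truth."""

    matrix: GenotypeMatrix
    cohort: PairCohort
    regions: RegionAnnotation
    expression: ExpressionMatrix
    truth: TruthRecord
    config: CohortConfig


# ---------------------------------------------------------------------------
# pieces
# ---------------------------------------------------------------------------


def simulate_frequencies(
    config: CohortConfig, rng: np.random.Generator, n_variants: int | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Ancestral and per-ancestry ALT frequencies (Balding-Nichols).

    Returns ``(p0, freqs)`` with ``freqs`` a variants x ancestries frame.
    With ``F = 0`` every ancestry shares the ancestral frequency exactly.
    """
    n = n_variants if n_variants is not None else config.n_variants
    f = config.ancestry.fst
    p0 = rng.uniform(0.05, 0.95, size=n)
    cols = {}
    for label in config.ancestry.labels:
        if f == 0.0:
            cols[label] = p0.copy()
        else:
            a = p0 * (1 - f) / f
            b = (1 - p0) * (1 - f) / f
            cols[label] = rng.beta(a, b)
    return p0, pd.DataFrame(cols)


def _sample_pair_structure(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Ancestry, relatedness class and donor status for every pair."""
    anc = config.ancestry
    rel = config.relatedness
    n = config.n_pairs
    rec_anc = rng.choice(anc.labels, size=n, p=anc.proportions)
    rel_idx = rng.choice(len(rel.ibd_fractions), size=n, p=rel.proportions)
    ibd = np.asarray(rel.ibd_fractions)[rel_idx]
    don_anc = np.where(
        ibd > 0, rec_anc, rng.choice(anc.labels, size=n, p=anc.proportions)
    )
    living = np.where(
        ibd > 0, True, rng.random(n) < rel.living_unrelated_fraction
    )
    return pd.DataFrame(
        {
            "recipient_ancestry": rec_anc,
            "donor_ancestry": don_anc,
            "expected_ibd": ibd,
            "donor_status": np.where(living, "living", "deceased"),
        }
    )


def simulate_pair_genotypes(
    config: CohortConfig,
    structure: pd.DataFrame,
    freqs: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Draw donor/recipient genotypes at the background loci.

    Returns ``(donor_calls, recipient_calls, pair_truth)`` where the calls
    are ``(n_pairs, n_loci)`` ALT counts and ``pair_truth`` holds the
    realized per-pair IBD fraction (half the fraction of loci at which one
    donor haplotype was copied IBD from the recipient).
    """
    n_loci = len(freqs)
    n = len(structure)
    donor = np.empty((n, n_loci), dtype=np.int8)
    recip = np.empty((n, n_loci), dtype=np.int8)
    true_ibd = np.zeros(n)
    for i, row in enumerate(structure.itertuples(index=False)):
        p_r = freqs[row.recipient_ancestry].to_numpy()
        p_d = freqs[row.donor_ancestry].to_numpy()
        hr1 = (rng.random(n_loci) < p_r).astype(np.int8)
        hr2 = (rng.random(n_loci) < p_r).astype(np.int8)
        hd2 = (rng.random(n_loci) < p_d).astype(np.int8)
        f = float(row.expected_ibd)
        if f > 0:
            mask = rng.random(n_loci) < 2 * f
            fresh = (rng.random(n_loci) < p_d).astype(np.int8)
            hd1 = np.where(mask, hr1, fresh).astype(np.int8)
            true_ibd[i] = mask.mean() / 2.0
        else:
            hd1 = (rng.random(n_loci) < p_d).astype(np.int8)
        donor[i] = hd1 + hd2
        recip[i] = hr1 + hr2
    truth = structure.copy()
    truth["true_ibd"] = true_ibd
    return donor, recip, truth


def _draw_block_haplotype(
    q: float, spec: BlockSpec, rng: np.random.Generator
) -> np.ndarray:
    """One haplotype's minor-allele indicator over the block members."""
    primary = rng.random() < q
    hap = np.full(spec.n_snps, primary, dtype=np.int8)
    if spec.recombinant_fraction > 0 and rng.random() < spec.recombinant_fraction:
        secondary = rng.random() < q
        cross = rng.integers(1, spec.n_snps)
        hap[cross:] = secondary
    return hap


def _simulate_locus(
    config: CohortConfig, structure: pd.DataFrame, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Block-member and tag genotypes for donors and recipients.

    The block and tag sit in one genomic region, so IBD sharing for related
    pairs is decided once per pair-haplotype for the whole locus.
    """
    n = len(structure)
    k = config.block.n_snps
    n_part = len(config.tag.partner_r2)
    # a partner mimics its tag haplotype except for a redraw with probability
    # 1 - sqrt(r2), giving haplotype correlation sqrt(r2) and hence LD ~ r2
    mutate_p = 1.0 - np.sqrt(np.asarray(config.tag.partner_r2, dtype=float))
    out = {
        "donor_block": np.zeros((n, k), dtype=np.int8),
        "recipient_block": np.zeros((n, k), dtype=np.int8),
        "donor_tag": np.zeros(n, dtype=np.int8),
        "recipient_tag": np.zeros(n, dtype=np.int8),
        "donor_partners": np.zeros((n, n_part), dtype=np.int8),
        "recipient_partners": np.zeros((n, n_part), dtype=np.int8),
        "donor_block_dosage": np.zeros(n, dtype=np.int8),
        "recipient_block_dosage": np.zeros(n, dtype=np.int8),
    }

    def partner_hap(tag_hap: np.int8, a: float) -> np.ndarray:
        redraw = rng.random(n_part) < mutate_p
        fresh = (rng.random(n_part) < a).astype(np.int8)
        return np.where(redraw, fresh, tag_hap).astype(np.int8)

    for i, row in enumerate(structure.itertuples(index=False)):
        q_r = config.block.minor_hap_freq[row.recipient_ancestry]
        q_d = config.block.minor_hap_freq[row.donor_ancestry]
        a_r = config.tag.risk_allele_freq[row.recipient_ancestry]
        a_d = config.tag.risk_allele_freq[row.donor_ancestry]
        br1 = _draw_block_haplotype(q_r, config.block, rng)
        br2 = _draw_block_haplotype(q_r, config.block, rng)
        tr1 = np.int8(rng.random() < a_r)
        tr2 = np.int8(rng.random() < a_r)
        pr1 = partner_hap(tr1, a_r)
        pr2 = partner_hap(tr2, a_r)
        bd2 = _draw_block_haplotype(q_d, config.block, rng)
        td2 = np.int8(rng.random() < a_d)
        pd2 = partner_hap(td2, a_d)
        f = float(row.expected_ibd)
        if f > 0 and rng.random() < 2 * f:
            bd1, td1, pd1 = br1, tr1, pr1
        else:
            bd1 = _draw_block_haplotype(q_d, config.block, rng)
            td1 = np.int8(rng.random() < a_d)
            pd1 = partner_hap(td1, a_d)
        out["donor_block"][i] = bd1 + bd2
        out["recipient_block"][i] = br1 + br2
        out["donor_tag"][i] = td1 + td2
        out["recipient_tag"][i] = tr1 + tr2
        if n_part:
            out["donor_partners"][i] = pd1 + pd2
            out["recipient_partners"][i] = pr1 + pr2
        # truth dosage: majority state over members (exact for intact haps)
        for side, g in (("donor", bd1 + bd2), ("recipient", br1 + br2)):
            vals, counts = np.unique(g, return_counts=True)
            out[f"{side}_block_dosage"][i] = vals[counts.argmax()]
    return out


def simulate_survival(
    eta: np.ndarray,
    hazard: HazardSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Exponential event times under the linear predictor ``eta``.

    The baseline rate is calibrated by bisection so the expected event rate
    under the censoring scheme ``C = min(horizon, Uniform(0, 2 horizon))``
    matches ``hazard.event_rate`` (within 1 percentage point in
    expectation).  Returns ``(time, event, lambda0)``.
    """
    eta = np.asarray(eta, dtype=float)
    h = hazard.horizon_days
    if h == 0:
        return np.full(len(eta), 1e-9), np.zeros(len(eta), dtype=int), 0.0

    rel = np.exp(eta - eta.mean())

    def expected_rate(lam0: float) -> float:
        lam = lam0 * rel
        x = lam * h
        with np.errstate(over="ignore"):
            p_admin = 1.0 - np.exp(-x)
        p_unif = 1.0 - np.where(x > 0, (1.0 - np.exp(-x)) / np.maximum(x, 1e-300), 1.0)
        return float(np.mean(0.5 * p_admin + 0.5 * p_unif))

    lo, hi = 1e-12, 1e3 / h
    if expected_rate(hi) < hazard.event_rate - 0.01:
        raise ValidationError(f"target event rate {hazard.event_rate} unattainable")
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if expected_rate(mid) < hazard.event_rate:
            lo = mid
        else:
            hi = mid
    lam0 = float(np.sqrt(lo * hi))
    achieved = expected_rate(lam0)
    if abs(achieved - hazard.event_rate) > 0.01:
        raise ValidationError(
            f"calibration failed: expected rate {achieved:.3f} vs target {hazard.event_rate}"
        )

    lam = lam0 * rel
    t_event = rng.exponential(1.0 / lam)
    censor = np.minimum(h, rng.uniform(0.0, 2.0 * h, size=len(eta)))
    event = (t_event <= censor).astype(int)
    time = np.maximum(np.minimum(t_event, censor), 1e-6)
    return time, event, lam0


def simulate_expression(
    dosage: np.ndarray,
    spec: EqtlSpec,
    sample_ids: list[str],
    rng: np.random.Generator,
    ancestry: np.ndarray | None = None,
) -> ExpressionMatrix:
    """Expression for one cis-regulated target gene plus noise genes.

    The target gene is ``baseline + effect * dosage + age/sex effects +
    Gaussian noise``; a planted coexpression module (``module_size`` genes
    at true correlation ``module_r`` with the target) can be added.  Values
    are clipped at 0 to stay on the log2(TPM + 1) scale.
    """
    n = len(sample_ids)
    dosage = np.asarray(dosage, dtype=float)
    age = np.clip(rng.normal(50, 13, size=n), 18, 85)
    sex = rng.integers(0, 2, size=n)
    cov = pd.DataFrame({"age": age, "sex": sex}, index=sample_ids)
    if ancestry is not None:
        cov["ancestry"] = ancestry

    genes = [spec.target_gene]
    target = (
        spec.baseline
        + spec.effect * dosage
        + spec.age_effect * (age - 50)
        + spec.sex_effect * sex
        + rng.normal(0, spec.noise_sd, size=n)
    )
    values = [target]
    z = (target - target.mean()) / max(target.std(), 1e-12)
    for j in range(spec.module_size):
        eps = rng.normal(0, 1, size=n)
        values.append(spec.baseline + spec.module_r * z + np.sqrt(1 - spec.module_r**2) * eps)
        genes.append(f"module_{j:03d}")
    n_noise = max(spec.n_genes - len(genes), 0)
    base = rng.uniform(2, 8, size=n_noise)
    for j in range(n_noise):
        values.append(base[j] + rng.normal(0, 1, size=n))
        genes.append(f"noise_{j:04d}")
    mat = pd.DataFrame(np.clip(np.vstack(values), 0, None), index=genes, columns=sample_ids)
    return ExpressionMatrix(mat, cov)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _variant_frame(config: CohortConfig) -> pd.DataFrame:
    """Variant metadata for the whole synthetic genome, sorted by (chrom, pos)."""
    rows = []
    # background on chr1 (genes first, then intergenic)
    for j in range(config.n_variants):
        rows.append(
            {
                "chrom": "chr1",
                "pos": 1_000_000 + 1_500 * j,
                "ref": "A",
                "alt": "G",
                "variant_id": f"v{j:06d}",
                "info_score": 1.0,
                "role": "background",
            }
        )
    for j in range(config.block.n_snps):
        rows.append(
            {
                "chrom": config.block.chrom,
                "pos": config.block.start_pos + config.block.spacing * j,
                "ref": "C",
                "alt": "T",
                "variant_id": f"blk{j:02d}",
                "info_score": 1.0,
                "role": "block",
            }
        )
    rows.append(
        {
            "chrom": config.block.chrom,
            "pos": config.block.start_pos + config.block.spacing * (config.block.n_snps + 5),
            "ref": "G",
            "alt": "A",  # ALT is the risk allele
            "variant_id": "tag_snp",
            "info_score": 1.0,
            "role": "tag",
        }
    )
    for j, _r2 in enumerate(config.tag.partner_r2):
        rows.append(
            {
                "chrom": config.block.chrom,
                "pos": config.block.start_pos + config.block.spacing * (config.block.n_snps + 6 + j),
                "ref": "T",
                "alt": "C",
                "variant_id": f"tag_partner{j}",
                "info_score": 1.0,
                "role": "tag_partner",
            }
        )
    qc = genotype_io.QCConfig()
    for j in range(config.n_mhc_decoys):
        rows.append(
            {
                "chrom": qc.mhc_chrom,
                "pos": qc.mhc_start + 10_000 * (j + 1),
                "ref": "A",
                "alt": "C",
                "variant_id": f"mhc{j:02d}",
                "info_score": 1.0,
                "role": "mhc_decoy",
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def _gene_regions(config: CohortConfig, variants: pd.DataFrame) -> RegionAnnotation:
    """Tile the leading background variants into contiguous gene bodies."""
    vpg = config.variants_per_gene
    bg = variants[variants["role"] == "background"].sort_values("pos")
    rows = []
    for g in range(config.n_genes):
        members = bg.iloc[g * vpg : (g + 1) * vpg]
        rows.append(
            {
                "chrom": "chr1",
                "start": int(members["pos"].min()) - 201,  # 0-based half-open
                "end": int(members["pos"].max()) + 200,
                "region_id": f"gene{g:04d}",
                "region_class": "gene",
            }
        )
    block_pos = variants.loc[variants["role"].isin(["block", "tag", "tag_partner"]), "pos"]
    rows.append(
        {
            "chrom": config.block.chrom,
            "start": int(block_pos.min()) - 501,
            "end": int(block_pos.max()) + 500,
            "region_id": "block_gene",
            "region_class": "gene",
        }
    )
    return RegionAnnotation(pd.DataFrame(rows))


def simulate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate a complete synthetic cohort (see module docstring).

    All randomness flows from ``seed`` (falling back to ``config.seed``);
    identical inputs give identical cohorts.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    variants = _variant_frame(config)
    structure = _sample_pair_structure(config, rng)
    n = config.n_pairs

    # background + decoy loci share the Balding-Nichols machinery
    n_bn = config.n_variants + config.n_mhc_decoys
    _, freqs = simulate_frequencies(config, rng, n_variants=n_bn)
    donor_bg, recip_bg, pair_truth = simulate_pair_genotypes(
        config, structure, freqs.iloc[: config.n_variants], rng
    )
    # decoys: unrelated draws (they are QC fodder, not score content)
    decoy_freqs = freqs.iloc[config.n_variants :].reset_index(drop=True)
    donor_dec = np.empty((n, config.n_mhc_decoys), dtype=np.int8)
    recip_dec = np.empty((n, config.n_mhc_decoys), dtype=np.int8)
    for i, row in enumerate(structure.itertuples(index=False)):
        p_d = decoy_freqs[row.donor_ancestry].to_numpy()
        p_r = decoy_freqs[row.recipient_ancestry].to_numpy()
        donor_dec[i] = rng.binomial(2, p_d)
        recip_dec[i] = rng.binomial(2, p_r)

    locus = _simulate_locus(config, structure, rng)

    # assemble calls in the sorted variant order
    bg_ids = [f"v{j:06d}" for j in range(config.n_variants)]
    order = variants["variant_id"].to_numpy()
    donor_calls = np.empty((n, len(variants)), dtype=np.int8)
    recip_calls = np.empty((n, len(variants)), dtype=np.int8)
    col_of = {vid: j for j, vid in enumerate(order)}
    bg_idx = [col_of[v] for v in bg_ids]
    donor_calls[:, bg_idx] = donor_bg
    recip_calls[:, bg_idx] = recip_bg
    blk_idx = [col_of[f"blk{j:02d}"] for j in range(config.block.n_snps)]
    donor_calls[:, blk_idx] = locus["donor_block"]
    recip_calls[:, blk_idx] = locus["recipient_block"]
    donor_calls[:, col_of["tag_snp"]] = locus["donor_tag"]
    recip_calls[:, col_of["tag_snp"]] = locus["recipient_tag"]
    for j in range(len(config.tag.partner_r2)):
        donor_calls[:, col_of[f"tag_partner{j}"]] = locus["donor_partners"][:, j]
        recip_calls[:, col_of[f"tag_partner{j}"]] = locus["recipient_partners"][:, j]
    dec_idx = [col_of[f"mhc{j:02d}"] for j in range(config.n_mhc_decoys)]
    donor_calls[:, dec_idx] = donor_dec
    recip_calls[:, dec_idx] = recip_dec

    # optionally rewrite the causal gene's variants as an intact LD cluster
    hz = config.hazard
    if hz.causal_gene is not None and hz.causal_gene_ld and hz.causal_gene.startswith("gene"):
        g = int(hz.causal_gene.removeprefix("gene"))
        vpg = config.variants_per_gene
        member_ids = bg_ids[g * vpg : (g + 1) * vpg]
        cols = [col_of[v] for v in member_ids]
        q = hz.causal_gene_minor_freq
        for i, row in enumerate(structure.itertuples(index=False)):
            br1 = np.int8(rng.random() < q)
            br2 = np.int8(rng.random() < q)
            bd2 = np.int8(rng.random() < q)
            f = float(row.expected_ibd)
            if f > 0 and rng.random() < 2 * f:
                bd1 = br1
            else:
                bd1 = np.int8(rng.random() < q)
            recip_calls[i, cols] = br1 + br2
            donor_calls[i, cols] = bd1 + bd2

    # low-info decoys: mark trailing background variants with poor INFO
    if config.n_low_info:
        low_ids = bg_ids[-config.n_low_info :]
        variants.loc[variants["variant_id"].isin(low_ids), "info_score"] = 0.2

    # sprinkle missingness
    if config.missing_rate > 0:
        for calls in (donor_calls, recip_calls):
            mask = rng.random(calls.shape) < config.missing_rate
            calls[mask] = MISSING

    sample_ids = []
    all_calls = np.empty((2 * n, len(variants)), dtype=np.int8)
    for i in range(n):
        sample_ids.extend([f"P{i:04d}D", f"P{i:04d}R"])
        all_calls[2 * i] = donor_calls[i]
        all_calls[2 * i + 1] = recip_calls[i]
    matrix = GenotypeMatrix(sample_ids, variants.drop(columns=["role"]), all_calls)

    # clinical covariates
    hla = np.clip(rng.poisson(3, size=n), 0, 6)
    induction = rng.choice(["depleting", "nondepleting"], size=n, p=(0.5, 0.5))
    pair_table = pd.DataFrame(
        {
            "donor_id": [f"P{i:04d}D" for i in range(n)],
            "recipient_id": [f"P{i:04d}R" for i in range(n)],
            "follow_time": 1.0,  # placeholder until survival is drawn
            "event": 0,
            "hla_mismatch": hla,
            "donor_status": structure["donor_status"],
            "induction": induction,
            "donor_ancestry": structure["donor_ancestry"],
            "recipient_ancestry": structure["recipient_ancestry"],
        }
    )
    cohort = PairCohort(pair_table)

    # mismatch scores on the clean (non-decoy) variants drive the hazard
    regions = _gene_regions(config, variants)
    table = mm.build_mismatch_table(matrix, cohort)
    clean = table.subset_variants(
        variants.loc[~variants["role"].eq("mhc_decoy"), "variant_id"].tolist()
    )
    gw = mm.genome_wide_score(clean)

    direction = classify_directions(
        locus["donor_block_dosage"],
        locus["recipient_block_dosage"],
        locus["donor_tag"],
        locus["recipient_tag"],
    )
    hz = config.hazard
    eta = hz.beta_genome_wide * gw.normalized
    eta = eta + hz.beta_minor_introducing * (direction == "MINOR_INTRODUCING").to_numpy(float)
    eta = eta + hz.beta_tag_risk * (direction == "TAG_RISK").to_numpy(float)
    gene_score = np.zeros(n)
    if hz.causal_gene is not None and hz.beta_gene != 0.0:
        sel = RegionAnnotation(regions.table[regions.table["region_id"] == hz.causal_gene])
        if len(sel) != 1:
            raise ValidationError(f"causal gene {hz.causal_gene!r} not in annotation")
        # dosage model: the hazard scales with the number of alien allele
        # copies introduced across the gene's variants, so single and double
        # mismatches carry one and two log-hazard units per variant
        member = sel.variant_membership(clean.variants).to_numpy()[:, 0]
        alien = np.where(clean.n_introduced[:, member] == MISSING, 0, clean.n_introduced[:, member])
        gene_score = alien.sum(axis=1).astype(float)
        eta = eta + hz.beta_gene * gene_score

    time, event, lam0 = simulate_survival(eta, hz, rng)
    cohort.table["follow_time"] = time
    cohort.table["event"] = event

    # expression for the recipients, driven by the recipient block dosage
    expression = simulate_expression(
        locus["recipient_block_dosage"].astype(float),
        config.eqtl,
        [f"P{i:04d}R" for i in range(n)],
        rng,
        ancestry=structure["recipient_ancestry"].to_numpy(),
    )

    variant_classes = pd.Series(
        rng.choice(
            ["non_exonic", "exonic", "transmembrane_nonsyn"],
            size=len(variants),
            p=(0.80, 0.15, 0.05),
        ),
        index=variants["variant_id"].to_numpy(),
        name="variant_class",
    )
    pair_truth = pair_truth.assign(
        donor_block_dosage=locus["donor_block_dosage"],
        recipient_block_dosage=locus["recipient_block_dosage"],
        donor_tag_gt=locus["donor_tag"],
        recipient_tag_gt=locus["recipient_tag"],
        direction_class=direction.to_numpy(),
        gene_score=gene_score,
        eta=eta,
        time=time,
        event=event,
    )
    truth = TruthRecord(
        pairs=pair_truth,
        variants=variants.assign(variant_class=variant_classes.to_numpy()),
        block_member_ids=[f"blk{j:02d}" for j in range(config.block.n_snps)],
        tag_id="tag_snp",
        betas={
            "beta_genome_wide": hz.beta_genome_wide,
            "beta_minor_introducing": hz.beta_minor_introducing,
            "beta_tag_risk": hz.beta_tag_risk,
            "beta_gene": hz.beta_gene,
        },
        genome_score_raw=gw.raw,
        genome_score_normalized=gw.normalized,
        lambda0=lam0,
    )
    logger.info(
        "simulated cohort: %d pairs, %d variants, %.1f%% events",
        n,
        len(variants),
        100 * event.mean(),
    )
    return SyntheticCohort(matrix, cohort, regions, expression, truth, config)


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------


def emit_cohort(
    config: CohortConfig | None = None,
    outdir: str | Path = ".",
    seed: int | None = None,
) -> SyntheticCohort:
    """Write all pipeline inputs (plus truth tables) to ``outdir``.

    Deterministic: identical config and seed give byte-identical files.
    """
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config, seed=seed)

    genotype_io.write_vcf(cohort.matrix, outdir / "genotypes.vcf")
    t = cohort.cohort.table.copy()
    t["follow_time"] = t["follow_time"].map(lambda v: f"{v:.4f}")
    t.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    genotype_io.write_regions(cohort.regions, outdir / "regions.bed")
    cohort.truth.variants[["variant_id", "variant_class"]].to_csv(
        outdir / "variant_classes.tsv", sep="\t", index=False
    )
    cohort.expression.values.to_csv(
        outdir / "expression.tsv", sep="\t", float_format="%.6f"
    )
    assert cohort.expression.covariates is not None
    cohort.expression.covariates.to_csv(
        outdir / "expression_covariates.tsv", sep="\t", float_format="%.6f", index_label="sample_id"
    )
    cohort.truth.pairs.to_csv(outdir / "truth_pairs.tsv", sep="\t", index=False, float_format="%.6f")
    cohort.truth.variants.to_csv(outdir / "truth_variants.tsv", sep="\t", index=False)
    # json round-trip turns tuples into lists so safe_dump stays plain YAML
    import json

    plain = json.loads(json.dumps(dataclasses.asdict(cohort.config)))
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(plain, fh, sort_keys=True)
    return cohort
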