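"""LD-defined haplotype blocks, haplotype dosage and mismatch directionality.

A haplotype block here is a set of variants in near-perfect linkage
disequilibrium (pairwise r-squared above a threshold, 0.99 by default)
treated as a single biallelic locus whose alleles are the minor and major
haplotypes.  A separate tag SNP — the rs893403 pattern — must be unlinked
to the block (r-squared below 0.5) and carries its own "risk mismatch"
definition: a donor introducing at least one risk allele into a recipient
homozygous for the non-risk allele.

Because genotypes are unphased, per-sample haplotype-allele dosage is
called by strict majority vote over the member SNPs' minor-allele counts;
in near-perfect LD the members almost always agree, and the vote's
discordance rate is reported as a per-sample quality measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, ValidationError
from .mismatch import introduced_allele_counts

logger = logging.getLogger(__name__)


class LDUndefinedError(ValueError):
    """LD is undefined for a monomorphic locus."""


class BlockTagLinkageError(ValueError):
    """Block members are linked to the tag SNP above the exclusion threshold."""


class DirectionClass(str, Enum):
    """Directionality classes for a pair's haplotype/tag mismatch status.

    ``TAG_RISK`` takes precedence regardless of haplotype mismatch status;
    ``MINOR_INTRODUCING`` is a donor introducing the minor haplotype allele
    into a homozygous-major recipient, ``MAJOR_INTRODUCING`` the converse,
    and ``OTHER`` covers pairs with no qualifying mismatch.
    """

    TAG_RISK = "TAG_RISK"
    MINOR_INTRODUCING = "MINOR_INTRODUCING"
    MAJOR_INTRODUCING = "MAJOR_INTRODUCING"
    OTHER = "OTHER"


# ---------------------------------------------------------------------------
# two-locus LD
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LDResult:
    """EM-estimated two-locus haplotype frequencies and r-squared."""

    id_a: str
    id_b: str
    r_squared: float
    hap_freqs: tuple[float, float, float, float]  # (AB, Ab, aB, ab); A/B = ALT
    n_samples: int


def pairwise_r2(
    gt_a: np.ndarray,
    gt_b: np.ndarray,
    id_a: str = "a",
    id_b: str = "b",
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> LDResult:
    """Estimate r-squared between two unphased genotype vectors.

    Two-locus haplotype frequencies are obtained by EM over the
    double-heterozygote phase ambiguity (converged when the largest
    frequency change is below ``tol`` or after ``max_iter`` iterations);
    r-squared is ``D^2 / (pA qA pB qB)``.
    """
    gt_a = np.asarray(gt_a)
    gt_b = np.asarray(gt_b)
    if gt_a.shape != gt_b.shape:
        raise ValidationError("genotype vectors must be aligned")
    ok = (gt_a != MISSING) & (gt_b != MISSING)
    a = gt_a[ok].astype(np.int64)
    b = gt_b[ok].astype(np.int64)
    n = int(ok.sum())
    if n == 0 or len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        raise LDUndefinedError(
            f"LD undefined for ({id_a}, {id_b}): monomorphic or empty after "
            "pairwise-complete filtering"
        )

    # fixed haplotype contributions from the 8 phase-unambiguous cells
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    # order: (AB, Ab, aB, ab) with A/B the ALT alleles
    fixed = np.zeros(4, dtype=float)
    contrib = {
        (0, 0): (0, 0, 0, 2),
        (0, 1): (0, 0, 1, 1),
        (0, 2): (0, 0, 2, 0),
        (1, 0): (0, 1, 0, 1),
        (1, 2): (1, 0, 1, 0),
        (2, 0): (0, 2, 0, 0),
        (2, 1): (1, 1, 0, 0),
        (2, 2): (2, 0, 0, 0),
    }
    for (i, j), hap in contrib.items():
        fixed += counts[i, j] * np.asarray(hap, dtype=float)
    n_dh = counts[1, 1]  # double heterozygotes: AB/ab vs Ab/aB unknown

    freqs = np.full(4, 0.25)
    for _ in range(max_iter):
        if n_dh:
            p_cis = freqs[0] * freqs[3]
            p_trans = freqs[1] * freqs[2]
            denom = p_cis + p_trans
            w = 0.5 if denom == 0 else p_cis / denom
            em = fixed + n_dh * np.array([w, 1 - w, 1 - w, w])
        else:
            em = fixed
        new = em / em.sum()
        delta = np.abs(new - freqs).max()
        freqs = new
        if delta < tol:
            break

    p_a = freqs[0] + freqs[1]
    p_b = freqs[0] + freqs[2]
    d = freqs[0] - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0:
        raise LDUndefinedError(f"LD undefined for ({id_a}, {id_b}): estimated monomorphic")
    r2 = float(np.clip(d * d / denom, 0.0, 1.0))
    return LDResult(id_a, id_b, r2, tuple(float(f) for f in freqs), n)


# ---------------------------------------------------------------------------
# block construction
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeBlock:
    """An ordered set of linked variants treated as one biallelic locus.

    ``minor_allele`` records, for each member, which allele (REF/ALT) sits
    on the minor haplotype; ``minor_hap_freq`` is the cohort frequency of
    that haplotype (< 0.5 by construction, ties resolved toward the
    ALT-bearing haplotype).
    """

    member_ids: list[str]  # ordered by genomic position
    minor_allele: dict[str, str]  # member id -> "REF" | "ALT"
    minor_hap_freq: float
    r2_in: float
    tag_id: str | None = None

    def __len__(self) -> int:
        return len(self.member_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.member_ids,
                "minor_allele": [self.minor_allele[m] for m in self.member_ids],
            }
        )


def _oriented_minor_counts(block: HaplotypeBlock, matrix: GenotypeMatrix) -> np.ndarray:
    """(samples x members) minor-allele counts, MISSING preserved."""
    cols = []
    ids = matrix.variants["variant_id"]
    for m in block.member_ids:
        idx = np.nonzero((ids == m).to_numpy())[0]
        if len(idx) != 1:
            raise ValidationError(f"block member {m!r} not present exactly once in matrix")
        g = matrix.calls[:, idx[0]].astype(np.int8)
        if block.minor_allele[m] == "REF":
            g = np.where(g == MISSING, MISSING, 2 - g).astype(np.int8)
        cols.append(g)
    return np.column_stack(cols)


def build_block(
    matrix: GenotypeMatrix,
    seed_variants: list[str],
    r2_in: float = 0.99,
    tag_variant: str | None = None,
    r2_out: float = 0.5,
) -> HaplotypeBlock:
    """Reduce candidate variants to a maximal clique of pairwise LD.

    Members whose pairwise r-squared with every other member reaches
    ``r2_in`` are kept; the member with the lowest connectivity is removed
    greedily until the clique condition holds (connectivity ties are broken
    by genomic position, earliest kept).  If ``tag_variant`` is given, every
    surviving member must have r-squared below ``r2_out`` with it —
    violations raise :class:`BlockTagLinkageError` listing the offenders.
    """
    ids = matrix.variants["variant_id"]
    pos = matrix.variants.set_index("variant_id")["pos"]
    missing = [s for s in seed_variants if not (ids == s).any()]
    if missing:
        raise ValidationError(f"seed variants absent from matrix: {missing[:5]}")
    members = sorted(dict.fromkeys(seed_variants), key=lambda v: int(pos[v]))

    def gvec(vid: str) -> np.ndarray:
        j = np.nonzero((ids == vid).to_numpy())[0][0]
        return matrix.calls[:, j]

    k = len(members)
    r2 = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r2[i, j] = r2[j, i] = pairwise_r2(
                gvec(members[i]), gvec(members[j]), members[i], members[j]
            ).r_squared

    alive = list(range(k))
    while len(alive) > 1:
        sub = r2[np.ix_(alive, alive)]
        conn = (sub >= r2_in).sum(axis=1) - 1  # exclude self
        if conn.min() == len(alive) - 1:
            break
        worst = conn.min()
        # among lowest-connectivity members drop the latest by position
        candidates = [alive[i] for i in range(len(alive)) if conn[i] == worst]
        alive.remove(max(candidates))
    kept = [members[i] for i in alive]

    if tag_variant is not None:
        tag_g = gvec(tag_variant)
        offenders = []
        for m in kept:
            if m == tag_variant:
                offenders.append((m, 1.0))
                continue
            r2_tag = pairwise_r2(gvec(m), tag_g, m, tag_variant).r_squared
            if r2_tag >= r2_out:
                offenders.append((m, r2_tag))
        if offenders:
            raise BlockTagLinkageError(
                f"block members linked to tag {tag_variant!r} at r2 >= {r2_out}: "
                + ", ".join(f"{m} (r2={v:.3f})" for m, v in offenders)
            )

    # orientation: which allele of each member sits on the minor haplotype
    ref_member = kept[0]
    ref_g = gvec(ref_member)
    ref_alt_freq = _alt_freq(ref_g)
    # the haplotype side anchored at the reference member's rarer allele;
    # exact 0.5 resolves toward ALT
    anchor_alt = ref_alt_freq <= 0.5
    minor_allele: dict[str, str] = {}
    hap_freqs = []
    for m in kept:
        if m == ref_member:
            aligned_alt = True
            f = ref_alt_freq
        else:
            ld = pairwise_r2(ref_g, gvec(m), ref_member, m)
            p_ab, p_a = ld.hap_freqs[0], ld.hap_freqs[0] + ld.hap_freqs[1]
            p_b = ld.hap_freqs[0] + ld.hap_freqs[2]
            aligned_alt = (p_ab - p_a * p_b) > 0  # ALT_m co-occurs with ALT_ref
            f = _alt_freq(gvec(m))
        on_minor_is_alt = aligned_alt == anchor_alt
        minor_allele[m] = "ALT" if on_minor_is_alt else "REF"
        hap_freqs.append(f if on_minor_is_alt else 1 - f)
    minor_hap_freq = float(np.mean(hap_freqs))

    block = HaplotypeBlock(kept, minor_allele, minor_hap_freq, r2_in, tag_variant)
    logger.info(
        "built haplotype block: %d/%d members kept, minor-haplotype frequency %.3f",
        len(kept),
        len(members),
        minor_hap_freq,
    )
    return block


def _alt_freq(g: np.ndarray) -> float:
    ok = g != MISSING
    return float(g[ok].sum() / (2.0 * ok.sum()))


# ---------------------------------------------------------------------------
# dosage and directionality
# ---------------------------------------------------------------------------


def haplotype_dosage(
    block: HaplotypeBlock, matrix: GenotypeMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample minor-haplotype dosage by strict majority vote.

    Returns ``(dosage, discordance)`` arrays over ``matrix.sample_ids``.
    A sample's dosage is the minor-allele count in {0, 1, 2} supported by a
    strict majority of its non-missing members; no strict majority (e.g. a
    15/15 split) or more than half the members missing yields ``MISSING``.
    Discordance is the fraction of non-missing members disagreeing with the
    call.
    """
    m = _oriented_minor_counts(block, matrix)  # samples x members
    k = m.shape[1]
    nonmiss = (m != MISSING).sum(axis=1)
    votes = np.stack([(m == v).sum(axis=1) for v in (0, 1, 2)], axis=1)
    top = votes.argmax(axis=1)
    top_votes = votes.max(axis=1)
    callable_ = (nonmiss * 2 >= k) & (nonmiss > 0) & (top_votes * 2 > nonmiss)
    dosage = np.where(callable_, top, MISSING).astype(np.int8)
    with np.errstate(invalid="ignore", divide="ignore"):
        disc = np.where(callable_, 1.0 - top_votes / np.maximum(nonmiss, 1), np.nan)
    return dosage, disc


def haplotype_mismatch(donor_dosage: int, recipient_dosage: int) -> tuple[int, str | None]:
    """Alien-allele count and direction treating the block as one locus.

    Applies the same containment rule as a variant mismatch with the minor
    haplotype playing the ALT role.  Returns ``(n_alien, direction)`` with
    direction ``"minor"`` or ``"major"`` for the introduced haplotype
    allele, or ``None`` when there is no mismatch.
    """
    for name, d in (("donor_dosage", donor_dosage), ("recipient_dosage", recipient_dosage)):
        if d not in (0, 1, 2):
            raise ValidationError(f"{name}={d} must be in {{0,1,2}}")
    n = int(introduced_allele_counts(np.array(donor_dosage), np.array(recipient_dosage)))
    if n == 0:
        return 0, None
    return n, "minor" if recipient_dosage == 0 else "major"


def tag_risk_mismatch(
    donor_tag_gt: int, recipient_tag_gt: int, risk_allele: str = "ALT"
) -> bool:
    """rs893403-style risk mismatch at the tag SNP.

    True iff the recipient is homozygous for the non-risk allele and the
    donor carries at least one risk allele.
    """
    if risk_allele not in ("REF", "ALT"):
        raise ValidationError("risk_allele must be 'REF' or 'ALT'")
    for name, g in (("donor_tag_gt", donor_tag_gt), ("recipient_tag_gt", recipient_tag_gt)):
        if g not in (0, 1, 2):
            raise ValidationError(f"{name}={g} must be in {{0,1,2}}")
    if risk_allele == "ALT":
        d_risk, r_risk = donor_tag_gt, recipient_tag_gt
    else:
        d_risk, r_risk = 2 - donor_tag_gt, 2 - recipient_tag_gt
    return r_risk == 0 and d_risk >= 1


def classify_direction(
    donor_dosage: int,
    recipient_dosage: int,
    donor_tag_gt: int,
    recipient_tag_gt: int,
    risk_allele: str = "ALT",
) -> DirectionClass:
    """Assign a pair to exactly one directionality class.

    The tag-SNP risk mismatch takes precedence regardless of the haplotype
    mismatch status (it defines its own group); then a minor-haplotype
    introduction into a homozygous-major recipient; then a major-haplotype
    introduction into a homozygous-minor recipient; everything else is
    ``OTHER``.
    """
    if tag_risk_mismatch(donor_tag_gt, recipient_tag_gt, risk_allele):
        return DirectionClass.TAG_RISK
    n, direction = haplotype_mismatch(donor_dosage, recipient_dosage)
    if n and direction == "minor":
        return DirectionClass.MINOR_INTRODUCING
    if n and direction == "major":
        return DirectionClass.MAJOR_INTRODUCING
    return DirectionClass.OTHER


def classify_directions(
    donor_dosage: np.ndarray,
    recipient_dosage: np.ndarray,
    donor_tag_gt: np.ndarray,
    recipient_tag_gt: np.ndarray,
    risk_allele: str = "ALT",
) -> pd.Series:
    """Vectorized :func:`classify_direction`; missing inputs yield NaN.

    Pairs with any missing dosage or tag genotype are excluded (NaN) with a
    logged count.
    """
    arrays = [np.asarray(a) for a in (donor_dosage, recipient_dosage, donor_tag_gt, recipient_tag_gt)]
    ok = np.all([a != MISSING for a in arrays], axis=0)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.warning("classify_directions: %d pair(s) excluded for missing dosage/genotype", n_excluded)
    out = pd.Series([None] * len(arrays[0]), dtype=object)
    for i in np.nonzero(ok)[0]:
        out.iloc[i] = classify_direction(
            int(arrays[0][i]), int(arrays[1][i]), int(arrays[2][i]), int(arrays[3][i]), risk_allele
        ).value
    return out
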