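"""Donor-recipient mismatch calls and multiscale mismatch scores.

A variant-level mismatch occurs when the donor carries an allele that the
recipient does not carry; the number of such "alien" allele copies the
donor would introduce grades the call as a single (1 copy) or double
(2 copies) mismatch.  A heterozygous recipient carries both alleles, so no
donor genotype can mismatch it.  Aggregation sums the 0/1 presence
indicator of the chosen mismatch class over a variant set (a gene body, a
functional class, or the whole genome outside the MHC) to a per-pair raw
score, which is normalized by the cohort interquartile range of the raw
scores so that scores are comparable across genotyping platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    PairCohort,
    RegionAnnotation,
    ValidationError,
)

logger = logging.getLogger(__name__)


class MismatchCategory(str, Enum):
    NONE = "NONE"
    SINGLE = "SINGLE"
    DOUBLE = "DOUBLE"
    MISSING = "MISSING"


@dataclass(frozen=True)
class MismatchCall:
    """One donor-recipient mismatch call at one variant."""

    category: MismatchCategory
    n_introduced: int  # copies of the alien allele the donor would introduce
    introduced_allele: str | None  # "REF", "ALT" or None


class NormalizationError(ValueError):
    """Raised when the cohort IQR of raw scores is zero."""


def variant_mismatch(donor_gt: int, recipient_gt: int) -> MismatchCall:
    """Classify one variant call by allele-set containment.

    The donor's allele multiset is tested for containment in the recipient's
    allele support: any donor allele copy absent from the recipient is an
    introduced ("alien") allele.  A heterozygous recipient therefore never
    has a mismatch.
    """
    for name, g in (("donor_gt", donor_gt), ("recipient_gt", recipient_gt)):
        if g not in (0, 1, 2, MISSING):
            raise ValidationError(f"{name}={g} not in {{0,1,2,MISSING}}")
    if donor_gt == MISSING or recipient_gt == MISSING:
        return MismatchCall(MismatchCategory.MISSING, 0, None)
    if recipient_gt == 0:
        n, allele = donor_gt, "ALT"
    elif recipient_gt == 2:
        n, allele = 2 - donor_gt, "REF"
    else:  # recipient carries both alleles
        n, allele = 0, None
    if n == 0:
        return MismatchCall(MismatchCategory.NONE, 0, None)
    cat = MismatchCategory.SINGLE if n == 1 else MismatchCategory.DOUBLE
    return MismatchCall(cat, n, allele)


def introduced_allele_counts(donor: np.ndarray, recipient: np.ndarray) -> np.ndarray:
    """Vectorized alien-allele count; MISSING propagates as ``MISSING``."""
    donor = np.asarray(donor)
    recipient = np.asarray(recipient)
    n = np.where(recipient == 0, donor, np.where(recipient == 2, 2 - donor, 0))
    n = np.where((donor == MISSING) | (recipient == MISSING), MISSING, n)
    return n.astype(np.int8)


@dataclass
class MismatchTable:
    """Pairs x variants alien-allele counts; the substrate for all scores.

    ``n_introduced`` holds values in ``{0, 1, 2, MISSING}``.  The derived
    indicators exclude missing cells (treated as 0 in sums; per-variant
    frequencies are computed over non-missing pairs only).
    """

    cohort: PairCohort
    variants: pd.DataFrame  # same schema as GenotypeMatrix.variants
    n_introduced: np.ndarray  # (n_pairs, n_variants) int8

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.n_introduced = np.asarray(self.n_introduced, dtype=np.int8)
        if self.n_introduced.shape != (self.cohort.n_pairs, len(self.variants)):
            raise ValidationError("n_introduced shape mismatch")

    @property
    def variant_ids(self) -> pd.Index:
        return pd.Index(self.variants["variant_id"])

    @property
    def missing_mask(self) -> np.ndarray:
        return self.n_introduced == MISSING

    @property
    def any_mismatch(self) -> np.ndarray:
        """0/1 indicator; missing cells are 0."""
        return (self.n_introduced >= 1).astype(np.uint8)

    @property
    def double_mismatch(self) -> np.ndarray:
        return (self.n_introduced == 2).astype(np.uint8)

    def indicator(self, mode: str) -> np.ndarray:
        if mode == "any":
            return self.any_mismatch
        if mode == "double":
            return self.double_mismatch
        raise ValidationError(f"mode must be 'any' or 'double', got {mode!r}")

    def subset_variants(self, variant_ids: Sequence[str]) -> "MismatchTable":
        mask = self.variants["variant_id"].isin(list(variant_ids)).to_numpy()
        return MismatchTable(self.cohort, self.variants.loc[mask], self.n_introduced[:, mask])

    def to_frame(self) -> pd.DataFrame:
        """Pairs x variants alien-allele counts (MISSING as -1), TSV-ready."""
        return pd.DataFrame(
            self.n_introduced,
            index=pd.RangeIndex(self.cohort.n_pairs, name="pair"),
            columns=self.variants["variant_id"].to_numpy(),
        )


def build_mismatch_table(matrix: GenotypeMatrix, cohort: PairCohort) -> MismatchTable:
    """Apply :func:`variant_mismatch` elementwise over the cohort."""
    cohort.validate(matrix)
    d_idx = [matrix.sample_index(s) for s in cohort.donor_ids]
    r_idx = [matrix.sample_index(s) for s in cohort.recipient_ids]
    n = introduced_allele_counts(matrix.calls[d_idx], matrix.calls[r_idx])
    return MismatchTable(cohort, matrix.variants, n)


def mismatch_frequency_filter(
    table: MismatchTable, min_freq: float = 0.05
) -> tuple[list[str], pd.DataFrame]:
    """Keep variants whose any-mismatch frequency is at least ``min_freq``.

    Frequencies are computed across pairs with non-missing calls.  Rarely
    mismatched variants are removed before gene- and variant-level screens
    so that gene scores are not driven by near-private mismatches; the
    genome-wide score deliberately does not use this filter.
    """
    if not 0.0 <= min_freq <= 1.0:
        raise ValidationError("min_freq must be in [0, 1]")
    nonmiss = (~table.missing_mask).sum(axis=0)
    hits = table.any_mismatch.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(nonmiss > 0, hits / np.maximum(nonmiss, 1), np.nan)
    keep = ~np.isnan(freq) & (freq >= min_freq)
    freq_table = pd.DataFrame(
        {
            "variant_id": table.variants["variant_id"],
            "n_pairs_nonmissing": nonmiss,
            "mismatch_freq": freq,
            "kept": keep,
        }
    )
    return table.variants.loc[keep, "variant_id"].tolist(), freq_table


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------


def iqr(values: np.ndarray, interpolation: str = "linear") -> float:
    """Interquartile range with linear-interpolation quantiles by default.

    The hinge convention is configurable (any numpy quantile method name)
    and logged, since published IQR normalizations rarely state it.
    """
    q75, q25 = np.percentile(np.asarray(values, dtype=float), [75, 25], method=interpolation)
    return float(q75 - q25)


@dataclass
class ScoreTable:
    """Per-pair raw and IQR-normalized mismatch scores at one scale."""

    scale: str  # 'genome_wide', 'gene:<id>' or 'class:<name>'
    pair_index: pd.Index
    raw: np.ndarray
    iqr: float | None = None
    normalized: np.ndarray | None = field(default=None)

    @classmethod
    def from_raw(
        cls,
        scale: str,
        pair_index: pd.Index,
        raw: np.ndarray,
        normalize: bool = True,
        interpolation: str = "linear",
        require_normalized: bool = False,
    ) -> "ScoreTable":
        raw = np.asarray(raw)
        width = iqr(raw, interpolation) if normalize else None
        normalized = None
        if normalize:
            if width == 0.0:
                if require_normalized:
                    raise NormalizationError(
                        f"IQR of raw scores at scale {scale!r} is zero; normalization "
                        "is undefined — use raw scores or a coarser scale"
                    )
                logger.warning("scale %s: zero IQR, normalized scores unavailable", scale)
                width = None
            else:
                normalized = raw / width
        return cls(scale, pair_index, raw, width, normalized)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"raw": self.raw}, index=self.pair_index)
        if self.normalized is not None:
            out["normalized"] = self.normalized
        return out


def region_score_matrix(
    table: MismatchTable, regions: RegionAnnotation, mode: str = "any"
) -> pd.DataFrame:
    """Raw per-pair scores for every region (pairs x regions).

    A variant inside several overlapping regions counts in each of them.
    Regions with no mapped variants score 0 and are logged.
    """
    if len(regions) == 0:
        raise ValidationError("empty region annotation")
    indicator = table.indicator(mode)
    membership = regions.variant_membership(table.variants)
    empty = membership.columns[~membership.to_numpy().any(axis=0)]
    if len(empty):
        logger.warning("%d region(s) contain no variants: %s", len(empty), list(empty[:5]))
    raw = indicator @ membership.to_numpy(dtype=np.int64)
    return pd.DataFrame(raw, index=pd.RangeIndex(table.cohort.n_pairs), columns=membership.columns)


def region_score(
    table: MismatchTable,
    regions: RegionAnnotation,
    mode: str = "any",
    normalize: bool = False,
) -> dict[str, ScoreTable]:
    """Per-region :class:`ScoreTable`\\ s (see :func:`region_score_matrix`)."""
    raw = region_score_matrix(table, regions, mode)
    return {
        rid: ScoreTable.from_raw(f"gene:{rid}", raw.index, raw[rid].to_numpy(), normalize=normalize)
        for rid in raw.columns
    }


def genome_wide_score(
    table: MismatchTable,
    exclude: RegionAnnotation | None = None,
    mode: str = "any",
    interpolation: str = "linear",
) -> ScoreTable:
    """Genome-wide mismatch burden outside ``exclude`` (typically the MHC).

    Uses every variant in the table — the low-mismatch-frequency filter is
    deliberately not applied at this scale.  Raises
    :class:`NormalizationError` if the cohort IQR is zero (e.g. a cohort of
    identical-genotype pairs), since the normalized score is then undefined.
    """
    indicator = table.indicator(mode)
    keep = np.ones(len(table.variants), dtype=bool)
    if exclude is not None and len(exclude):
        membership = exclude.variant_membership(table.variants)
        keep = ~membership.to_numpy().any(axis=1)
    raw = indicator[:, keep].sum(axis=1)
    return ScoreTable.from_raw(
        "genome_wide",
        pd.RangeIndex(table.cohort.n_pairs),
        raw,
        interpolation=interpolation,
        require_normalized=True,
    )


def class_scores(
    table: MismatchTable,
    variant_classes: pd.Series | np.ndarray,
    mode: str = "any",
    allowed: Sequence[str] = ("exonic", "non_exonic", "transmembrane_nonsyn"),
) -> tuple[dict[str, ScoreTable], pd.DataFrame]:
    """Genome-wide-style scores restricted to functional variant classes.

    ``variant_classes`` gives one label per variant in the table.  Returns
    the per-class score tables and the Pearson correlation matrix of the
    class raw scores across pairs — a collinearity check: when class burdens
    are highly correlated their effects cannot be dissected.
    """
    labels = np.asarray(variant_classes)
    if labels.shape[0] != len(table.variants):
        raise ValidationError("variant_classes length does not match table")
    unknown = set(np.unique(labels)) - set(allowed)
    if unknown:
        raise ValidationError(f"unknown class labels: {sorted(unknown)}")
    indicator = table.indicator(mode)
    out: dict[str, ScoreTable] = {}
    raws = {}
    for cls in allowed:
        mask = labels == cls
        raw = indicator[:, mask].sum(axis=1)
        if not mask.any():
            logger.warning("class %s has no variants; degenerate score", cls)
        out[cls] = ScoreTable.from_raw(
            f"class:{cls}", pd.RangeIndex(table.cohort.n_pairs), raw, normalize=mask.any()
        )
        raws[cls] = raw
    corr = pd.DataFrame(raws).corr()
    return out, corr


# ---------------------------------------------------------------------------
# relatedness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PibdEstimate:
    """Method-of-moments kinship estimate pihat = P(IBD=1)/2 + P(IBD=2)."""

    pihat: float
    n_sites: int
    low_confidence: bool  # fewer than the configured number of informative sites


def estimate_pibd(
    gt_i: np.ndarray,
    gt_j: np.ndarray,
    allele_freqs: np.ndarray,
    min_maf: float = 0.05,
    min_sites: int = 100,
) -> PibdEstimate:
    """Estimate the proportion of genome shared identity-by-descent.

    Uses the genomic-relationship moment estimator
    ``mean[(g_i - 2p)(g_j - 2p) / (2 p (1 - p))]`` over pairwise-complete
    common variants (MAF >= ``min_maf``), truncated to ``[0, 1]``.  Its
    expectation for an outbred pair equals pihat: ~1 for self, ~0.5 for
    parent-offspring, ~0 for unrelated individuals drawn from the supplied
    frequencies.
    """
    gt_i = np.asarray(gt_i, dtype=float)
    gt_j = np.asarray(gt_j, dtype=float)
    p = np.asarray(allele_freqs, dtype=float)
    if not (gt_i.shape == gt_j.shape == p.shape):
        raise ValidationError("genotype vectors and frequencies must be aligned")
    ok = (
        (gt_i != MISSING)
        & (gt_j != MISSING)
        & (p > 0.0)
        & (p < 1.0)
        & (np.minimum(p, 1 - p) >= min_maf)
    )
    n_sites = int(ok.sum())
    if n_sites == 0:
        raise ValidationError("no informative sites for pIBD estimation")
    pi = p[ok]
    contrib = (gt_i[ok] - 2 * pi) * (gt_j[ok] - 2 * pi) / (2 * pi * (1 - pi))
    pihat = float(np.clip(contrib.mean(), 0.0, 1.0))
    low = n_sites < min_sites
    if low:
        logger.warning("pIBD estimate from only %d informative sites", n_sites)
    return PibdEstimate(pihat, n_sites, low)
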