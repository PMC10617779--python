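"""Genotype, pairing and region I/O plus cohort-level variant quality control.

This module owns the coding conventions used by the whole package:

* genotypes are ALT-allele counts in ``{0, 1, 2}`` with :data:`MISSING`
  (``-1``) for no-calls;
* VCF-facing positions are 1-based inclusive, region intervals are stored
  0-based half-open (BED convention);
* variants are biallelic only — multiallelic records are rejected, not
  decomposed, because the mismatch definition is stated on allele presence
  and no decomposition rule would be principled.

Imputation, phasing and sample-level QC are upstream concerns and are not
performed here.  The only imputation-related rule that lives in this module
is posterior masking: an imputed genotype whose maximum genotype posterior
falls below a threshold (0.95 by default in :class:`QCConfig`) is set to
missing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING: int = -1

_VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "variant_id", "info_score"]

_PAIR_COLUMNS = [
    "donor_id",
    "recipient_id",
    "follow_time",
    "event",
    "hla_mismatch",
    "donor_status",
    "induction",
    "donor_ancestry",
    "recipient_ancestry",
]


class ValidationError(ValueError):
    """An input violates a documented invariant."""


class MultiallelicRecordError(ValidationError):
    """A VCF record carries more than one ALT allele."""


class VcfParseError(ValidationError):
    """The VCF file could not be parsed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x biallelic variants, calls coded as ALT-allele counts.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per row of ``calls``.
    variants
        Per-variant table with columns ``chrom, pos, ref, alt, variant_id,
        info_score`` sorted by ``(chrom, pos)``.  ``pos`` is 1-based.
        ``info_score`` is the imputation INFO score in ``[0, 1]`` or NaN.
    calls
        ``(n_samples, n_variants)`` int8 array with values in
        ``{0, 1, 2, MISSING}``.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample_ids are not unique")
        missing_cols = set(_VARIANT_COLUMNS) - set(self.variants.columns)
        if missing_cols:
            raise ValidationError(f"variant table lacks columns {sorted(missing_cols)}")
        if self.variants["variant_id"].duplicated().any():
            dup = self.variants.loc[self.variants["variant_id"].duplicated(), "variant_id"]
            raise ValidationError(f"duplicate variant ids: {list(dup.head())}")
        if self.calls.shape != (len(self.sample_ids), len(self.variants)):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError("calls contain values outside {0,1,2,MISSING}")
        order = self.variants.sort_values(["chrom", "pos"], kind="mergesort").index
        if not np.array_equal(order.to_numpy(), np.arange(len(self.variants))):
            raise ValidationError("variants are not sorted by (chrom, pos)")

    # -- accessors ----------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> pd.Index:
        return pd.Index(self.variants["variant_id"])

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise ValidationError(f"unknown sample id {sample_id!r}") from None

    def genotypes(self, sample_id: str) -> np.ndarray:
        return self.calls[self.sample_index(sample_id)]

    def subset_variants(self, keep: np.ndarray | Sequence[str]) -> "GenotypeMatrix":
        """Return a matrix restricted to a boolean mask or list of variant ids."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            mask = keep
        else:
            mask = self.variants["variant_id"].isin(list(keep)).to_numpy()
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=self.variants.loc[mask],
            calls=self.calls[:, mask],
        )

    def allele_frequencies(self) -> np.ndarray:
        """ALT-allele frequency per variant over non-missing calls (NaN if none)."""
        calls = self.calls
        nonmiss = (calls != MISSING).sum(axis=0)
        alt = np.where(calls == MISSING, 0, calls).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(nonmiss > 0, alt / (2.0 * nonmiss), np.nan)


@dataclass
class PairCohort:
    """Donor-recipient pairings with survival outcome and covariates.

    ``table`` has one row per pair and the columns listed in
    ``_PAIR_COLUMNS``: ``follow_time`` in days (> 0), ``event`` the
    death-censored graft-loss indicator in ``{0, 1}``, ``hla_mismatch`` a
    non-negative HLA mismatch count, ``donor_status`` in
    ``{living, deceased}``, ``induction`` a categorical therapy label and
    ancestry labels for both members.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        self.validate()

    def validate(self, matrix: GenotypeMatrix | None = None) -> None:
        missing = set(_PAIR_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValidationError(f"pair table lacks columns {sorted(missing)}")
        t = self.table
        if (t["follow_time"] <= 0).any():
            bad = t.index[t["follow_time"] <= 0].tolist()
            raise ValidationError(f"non-positive follow_time at rows {bad[:5]}")
        if not t["event"].isin([0, 1]).all():
            raise ValidationError("event must be 0 or 1")
        if (t["hla_mismatch"] < 0).any():
            raise ValidationError("hla_mismatch must be non-negative")
        if not t["donor_status"].isin(["living", "deceased"]).all():
            raise ValidationError("donor_status must be 'living' or 'deceased'")
        if matrix is not None:
            ids = set(matrix.sample_ids)
            for col in ("donor_id", "recipient_id"):
                unknown = set(t[col]) - ids
                if unknown:
                    raise ValidationError(
                        f"{col} values absent from genotype matrix: {sorted(unknown)[:5]}"
                    )

    @property
    def n_pairs(self) -> int:
        return len(self.table)

    @property
    def donor_ids(self) -> list[str]:
        return self.table["donor_id"].tolist()

    @property
    def recipient_ids(self) -> list[str]:
        return self.table["recipient_id"].tolist()


@dataclass
class RegionAnnotation:
    """Genomic regions, stored 0-based half-open (BED convention).

    A region with ``start=s, end=e`` covers 1-based positions ``s+1 .. e``.
    ``region_class`` distinguishes gene bodies from the MHC interval,
    functional variant classes, or custom sets; ids must be unique within a
    class.
    """

    table: pd.DataFrame

    VALID_CLASSES = {"gene", "MHC", "exonic", "non_exonic", "transmembrane_nonsyn", "custom"}

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        required = {"chrom", "start", "end", "region_id", "region_class"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"region table lacks columns {sorted(missing)}")
        t = self.table
        if (t["start"] >= t["end"]).any():
            raise ValidationError("regions require start < end (0-based half-open)")
        bad = set(t["region_class"]) - self.VALID_CLASSES
        if bad:
            raise ValidationError(f"unknown region classes: {sorted(bad)}")
        if t.duplicated(["region_class", "region_id"]).any():
            raise ValidationError("region_ids must be unique within a class")

    def __len__(self) -> int:
        return len(self.table)

    def of_class(self, region_class: str) -> "RegionAnnotation":
        return RegionAnnotation(self.table[self.table["region_class"] == region_class])

    def variant_membership(self, variants: pd.DataFrame) -> pd.DataFrame:
        """Boolean membership matrix: variants x regions (1-based pos containment)."""
        chrom = variants["chrom"].to_numpy()
        pos = variants["pos"].to_numpy()
        out = {}
        for _, r in self.table.iterrows():
            out[r["region_id"]] = (chrom == r["chrom"]) & (pos > r["start"]) & (pos <= r["end"])
        return pd.DataFrame(out, index=variants["variant_id"].to_numpy())


@dataclass
class QCConfig:
    """Variant quality-control thresholds.

    Defaults follow standard imputation-cohort practice: variants with
    imputation INFO score below 0.4, missing rate above 0.05, minor allele
    frequency below 0.01, or a Hardy-Weinberg exact p-value below 1e-6 are
    removed, genotype posteriors below 0.95 are masked to missing at read
    time, and the extended MHC interval chr6:28,866,528-33,775,446 (hg19,
    1-based inclusive) is excluded so HLA itself never contributes to
    non-HLA mismatch scores.
    """

    max_missing_rate: float = 0.05
    min_maf: float = 0.01
    min_hwe_p: float = 1e-6
    min_info: float = 0.4
    min_posterior: float = 0.95
    mhc_chrom: str = "chr6"
    mhc_start: int = 28866528  # 1-based inclusive
    mhc_end: int = 33775446
    min_mismatch_freq: float = 0.05

    def __post_init__(self) -> None:
        for name in ("max_missing_rate", "min_maf", "min_posterior", "min_mismatch_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.min_hwe_p <= 1.0:
            raise ValidationError("min_hwe_p must be in (0, 1]")
        if not 0.0 <= self.min_info <= 1.0:
            raise ValidationError("min_info must be in [0, 1]")
        if self.mhc_start > self.mhc_end:
            raise ValidationError("mhc_start > mhc_end")


#: Fixed order in which the per-variant filters are applied; each removed
#: variant is attributed to the first filter it fails, so QC reports are
#: deterministic and reconcile exactly.
QC_FILTER_ORDER = ["info_score", "missing_rate", "monomorphic", "maf", "hwe", "mhc"]


@dataclass
class QCReport:
    """Per-filter removal counts; ``input = surviving + sum(removed)``."""

    n_input: int
    n_surviving: int
    removed: dict[str, list[str]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.removed.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"filter": k, "n_removed": len(self.removed.get(k, []))} for k in QC_FILTER_ORDER]
        rows.append({"filter": "surviving", "n_removed": self.n_surviving})
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path, min_posterior: float | None = None) -> GenotypeMatrix:
    """Read a biallelic VCF into a :class:`GenotypeMatrix`.

    Genotypes are coded as ALT-allele counts.  If the FORMAT field ``GP``
    (genotype posteriors) is present and ``min_posterior`` is given, any
    genotype whose maximum posterior falls below the threshold is masked to
    :data:`MISSING`; masking never changes the value of a call that stays
    non-missing.  Multiallelic records are rejected.

    Raises
    ------
    VcfParseError
        if the file cannot be parsed.
    MultiallelicRecordError
        naming the offending record.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VcfParseError(f"cannot parse VCF {path!r}: {exc}") from exc

    sample_ids = list(vcf.samples)
    rows = []
    call_cols: list[np.ndarray] = []
    try:
        for v in vcf:
            alts = [a for a in v.ALT if a not in (None, ".")]
            if len(alts) != 1:
                raise MultiallelicRecordError(
                    f"record {v.CHROM}:{v.POS} {v.REF}>{','.join(v.ALT) or '.'} "
                    "is not biallelic; split or drop multiallelic sites upstream"
                )
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = np.asarray(v.gt_types, dtype=np.int8)
            calls = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING).astype(np.int8)
            if min_posterior is not None:
                try:
                    gp = v.format("GP")
                except KeyError:
                    gp = None
                if gp is not None:
                    maxp = np.nanmax(np.asarray(gp, dtype=float), axis=1)
                    calls = np.where(maxp < min_posterior, MISSING, calls).astype(np.int8)
            info = v.INFO.get("INFO")
            if info is None:
                info = v.INFO.get("R2")
            vid = v.ID or f"{v.CHROM}:{v.POS}:{v.REF}:{alts[0]}"
            rows.append(
                {
                    "chrom": v.CHROM,
                    "pos": v.POS,
                    "ref": v.REF,
                    "alt": alts[0],
                    "variant_id": vid,
                    "info_score": float(info) if info is not None else np.nan,
                }
            )
            call_cols.append(calls)
    except MultiallelicRecordError:
        raise
    except Exception as exc:
        raise VcfParseError(f"malformed VCF {path!r} near record {len(rows) + 1}: {exc}") from exc

    if not rows:
        raise VcfParseError(f"VCF {path!r} contains no records")
    variants = pd.DataFrame(rows)
    calls = np.column_stack(call_cols).astype(np.int8)
    order = variants.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
    return GenotypeMatrix(sample_ids, variants.iloc[order], calls[:, order])


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF 4.2 file (deterministic byte output)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(matrix.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.sample_ids) + "\n")
        for j, (_, v) in enumerate(matrix.variants.iterrows()):
            info = "." if pd.isna(v["info_score"]) else f"INFO={v['info_score']:.4f}"
            gts = "\t".join(gt_map[int(g)] for g in matrix.calls[:, j])
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['variant_id']}\t{v['ref']}\t{v['alt']}"
                f"\t.\t.\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote configurations no more probable than the observed one
    (Wigginton-Cutler-Abecasis construction).  Returns a p-value in (0, 1].
    """
    for name, v in (("n_hom_ref", n_hom_ref), ("n_het", n_het), ("n_hom_alt", n_hom_alt)):
        if v < 0 or v != int(v):
            raise ValidationError(f"{name}={v} must be a non-negative integer")
    a, h, b = int(n_hom_ref), int(n_het), int(n_hom_alt)
    n = a + h + b
    if n < 1:
        raise ValidationError("at least one genotype required")
    n_ref = 2 * a + h
    n_alt = 2 * b + h
    rare = min(n_ref, n_alt)
    if rare == 0:
        return 1.0

    lg = math.lgamma

    def logprob(het: int) -> float:
        hom_ref = (n_ref - het) // 2
        hom_alt = (n_alt - het) // 2
        return (
            lg(n + 1) - lg(hom_ref + 1) - lg(het + 1) - lg(hom_alt + 1)
            + het * math.log(2.0)
            + lg(n_ref + 1) + lg(n_alt + 1) - lg(2 * n + 1)
        )

    hets = np.arange(rare % 2, rare + 1, 2)
    logp = np.array([logprob(int(x)) for x in hets])
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == h][0]
    # slack absorbs float noise on exact probability ties (symmetric configs)
    p = float(probs[probs <= p_obs * (1.0 + 1e-9)].sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


def apply_qc(
    matrix: GenotypeMatrix,
    config: QCConfig | None = None,
    hwe_sample_ids: Sequence[str] | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter variants in the fixed order of :data:`QC_FILTER_ORDER`.

    Each variant is attributed to the first filter it fails, so the report
    counts reconcile exactly with the input.  The Hardy-Weinberg test is
    computed across all samples by default; pass ``hwe_sample_ids`` (for
    example recipients plus living donors, to avoid double-counting related
    genomes) to restrict it.  QC is idempotent.
    """
    config = config or QCConfig()
    calls = matrix.calls
    n_in = matrix.n_variants
    variant_ids = matrix.variants["variant_id"].to_numpy()

    failed: dict[str, np.ndarray] = {}

    info = matrix.variants["info_score"].to_numpy(dtype=float)
    failed["info_score"] = ~np.isnan(info) & (info < config.min_info)

    miss_rate = (calls == MISSING).mean(axis=0)
    failed["missing_rate"] = miss_rate > config.max_missing_rate

    freqs = matrix.allele_frequencies()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freqs, 1.0 - freqs)
    failed["monomorphic"] = np.isnan(maf) | (maf == 0.0)
    failed["maf"] = maf < config.min_maf

    if hwe_sample_ids is None:
        hwe_calls = calls
    else:
        idx = [matrix.sample_index(s) for s in hwe_sample_ids]
        hwe_calls = calls[idx]
    hwe_fail = np.zeros(n_in, dtype=bool)
    # only test variants still alive after earlier filters (saves work; the
    # attribution result is identical because earlier failures win anyway)
    alive = ~(failed["info_score"] | failed["missing_rate"] | failed["monomorphic"] | failed["maf"])
    for j in np.nonzero(alive)[0]:
        col = hwe_calls[:, j]
        a = int((col == 0).sum())
        h = int((col == 1).sum())
        b = int((col == 2).sum())
        if a + h + b >= 1:
            hwe_fail[j] = hwe_exact_test(a, h, b) < config.min_hwe_p
    failed["hwe"] = hwe_fail

    chrom = matrix.variants["chrom"].astype(str).to_numpy()
    pos = matrix.variants["pos"].to_numpy()
    chrom_norm = np.char.lstrip(chrom.astype(str), "chr")
    mhc_chrom = config.mhc_chrom.removeprefix("chr")
    failed["mhc"] = (
        (chrom_norm == mhc_chrom) & (pos >= config.mhc_start) & (pos <= config.mhc_end)
    )

    removed: dict[str, list[str]] = {}
    attributed = np.zeros(n_in, dtype=bool)
    for name in QC_FILTER_ORDER:
        hit = failed[name] & ~attributed
        removed[name] = [str(v) for v in variant_ids[hit]]
        attributed |= hit

    keep = ~attributed
    out = matrix.subset_variants(keep)
    report = QCReport(n_input=n_in, n_surviving=int(keep.sum()), removed=removed)
    logger.info(
        "QC: %d -> %d variants (%s)",
        n_in,
        report.n_surviving,
        ", ".join(f"{k}={v}" for k, v in report.counts.items() if v),
    )
    return out, report


# ---------------------------------------------------------------------------
# tabular inputs
# ---------------------------------------------------------------------------


def read_pairs(path: str | Path) -> PairCohort:
    """Read the D-R pairing table (TSV with header) and validate it."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"pair table {path!s} lacks columns {sorted(missing)}")
    return PairCohort(df)


def write_pairs(cohort: PairCohort, path: str | Path) -> None:
    cohort.table.to_csv(path, sep="\t", index=False)


def read_regions(path: str | Path, default_class: str = "gene") -> RegionAnnotation:
    """Read a BED file (0-based half-open; 4 columns, optional 5th = class)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "region_id", "region_class"],
    )
    if df["region_id"].isna().any():
        raise ValidationError(f"BED {path!s} needs 4 columns (chrom start end name)")
    df["region_class"] = df["region_class"].fillna(default_class)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return RegionAnnotation(df)


def write_regions(regions: RegionAnnotation, path: str | Path) -> None:
    regions.table[["chrom", "start", "end", "region_id", "region_class"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def mhc_region(config: QCConfig | None = None) -> RegionAnnotation:
    """The configured MHC interval as a single-region annotation."""
    config = config or QCConfig()
    return RegionAnnotation(
        pd.DataFrame(
            {
                "chrom": [config.mhc_chrom],
                "start": [config.mhc_start - 1],  # 1-based inclusive -> 0-based half-open
                "end": [config.mhc_end],
                "region_id": ["MHC"],
                "region_class": ["MHC"],
            }
        )
    )
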