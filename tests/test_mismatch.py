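"""Variant mismatch calls, multiscale scores and the pIBD estimator."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drmatch.genotype_io import MISSING, RegionAnnotation, ValidationError
from drmatch.mismatch import (
    MismatchCategory,
    MismatchTable,
    NormalizationError,
    ScoreTable,
    build_mismatch_table,
    class_scores,
    estimate_pibd,
    genome_wide_score,
    introduced_allele_counts,
    iqr,
    mismatch_frequency_filter,
    region_score,
    region_score_matrix,
    variant_mismatch,
)

from conftest import make_cohort, make_matrix


def containment_oracle(donor: int, recipient: int) -> int:
    """Alien-allele count by explicit multiset containment (0=REF, 1=ALT)."""
    donor_alleles = [1] * donor + [0] * (2 - donor)
    recipient_support = {1} if recipient >= 1 else set()
    recipient_support |= {0} if recipient <= 1 else set()
    return sum(1 for a in donor_alleles if a not in recipient_support)


class TestVariantMismatch:
    def test_agrees_with_containment_oracle_on_all_nine_combinations(self):
        expected_cat = {0: MismatchCategory.NONE, 1: MismatchCategory.SINGLE, 2: MismatchCategory.DOUBLE}
        for d in (0, 1, 2):
            for r in (0, 1, 2):
                call = variant_mismatch(d, r)
                n = containment_oracle(d, r)
                assert call.n_introduced == n, (d, r)
                assert call.category == expected_cat[n]

    def test_grid_matches_stated_table(self):
        table = {
            (0, 0): "NONE", (1, 0): "SINGLE", (2, 0): "DOUBLE",
            (0, 1): "NONE", (1, 1): "NONE", (2, 1): "NONE",
            (0, 2): "DOUBLE", (1, 2): "SINGLE", (2, 2): "NONE",
        }
        for (d, r), cat in table.items():
            assert variant_mismatch(d, r).category.value == cat

    def test_heterozygous_recipient_never_mismatched(self):
        for d in (0, 1, 2):
            assert variant_mismatch(d, 1).category == MismatchCategory.NONE

    def test_direction_asymmetry(self):
        a = variant_mismatch(1, 0)
        b = variant_mismatch(0, 1)
        assert a.category == MismatchCategory.SINGLE
        assert b.category == MismatchCategory.NONE  # recipient het carries both
        # the true asymmetry witness: donor het into hom-ref vs hom-alt
        c = variant_mismatch(1, 2)
        assert a.introduced_allele == "ALT" and c.introduced_allele == "REF"

    def test_missing_propagates(self):
        assert variant_mismatch(MISSING, 0).category == MismatchCategory.MISSING
        assert variant_mismatch(2, MISSING).category == MismatchCategory.MISSING

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            variant_mismatch(3, 0)

    @given(
        d=st.integers(0, 2).map(np.int8),
        r=st.integers(0, 2).map(np.int8),
    )
    @settings(deadline=None, derandomize=True)
    def test_vectorized_matches_scalar(self, d, r):
        assert int(introduced_allele_counts(np.array([d]), np.array([r]))[0]) == (
            variant_mismatch(int(d), int(r)).n_introduced
        )


class TestMismatchTable:
    def test_per_pair_categories(self):
        m = make_matrix([[1, 2, 0], [0, 2, 2]], sample_ids=["D", "R"])
        cohort = make_cohort([("D", "R")])
        table = build_mismatch_table(m, cohort)
        assert table.n_introduced.tolist() == [[1, 0, 2]]

    def test_self_pair_all_none(self, rng):
        calls = rng.integers(0, 3, size=(1, 20)).astype(np.int8)
        m = make_matrix(calls, sample_ids=["X"])
        table = build_mismatch_table(m, make_cohort([("X", "X")]))
        assert (table.n_introduced == 0).all()

    def test_missing_cell_propagates(self):
        m = make_matrix([[MISSING], [0]], sample_ids=["D", "R"])
        table = build_mismatch_table(m, make_cohort([("D", "R")]))
        assert table.n_introduced[0, 0] == MISSING
        assert table.any_mismatch[0, 0] == 0  # excluded from indicators

    def test_double_implies_any(self, rng):
        d = rng.integers(0, 3, size=(50, 40)).astype(np.int8)
        r = rng.integers(0, 3, size=(50, 40)).astype(np.int8)
        n = introduced_allele_counts(d, r)
        any_ = (n >= 1) & (n != MISSING)
        double = n == 2
        assert (double <= any_).all()

    def test_unknown_sample_rejected(self):
        m = make_matrix([[0]], sample_ids=["A"])
        with pytest.raises(ValidationError):
            build_mismatch_table(m, make_cohort([("A", "nope")]))


class TestFrequencyFilter:
    def _table(self, n_mismatched_pairs: int, n_pairs: int = 20) -> MismatchTable:
        donors = np.zeros((n_pairs, 1), dtype=np.int8)
        donors[:n_mismatched_pairs] = 1
        calls = np.vstack([donors, np.zeros((n_pairs, 1), dtype=np.int8)])
        ids = [f"D{i}" for i in range(n_pairs)] + [f"R{i}" for i in range(n_pairs)]
        m = make_matrix(calls, sample_ids=ids)
        cohort = make_cohort([(f"D{i}", f"R{i}") for i in range(n_pairs)])
        return build_mismatch_table(m, cohort)

    def test_never_mismatched_removed(self):
        kept, _ = mismatch_frequency_filter(self._table(0), 0.05)
        assert kept == []

    def test_boundary_frequency_kept(self):
        # 1 of 20 pairs -> frequency exactly 0.05 is retained
        kept, freq = mismatch_frequency_filter(self._table(1), 0.05)
        assert kept == ["var0"]
        assert freq["mismatch_freq"].iloc[0] == pytest.approx(0.05)

    def test_engineered_frequencies_hand_count(self):
        # variants mismatched in 0..9 of 10 pairs
        n_pairs = 10
        donors = np.zeros((n_pairs, 10), dtype=np.int8)
        for j in range(10):
            donors[:j, j] = 1
        calls = np.vstack([donors, np.zeros((n_pairs, 10), dtype=np.int8)])
        ids = [f"D{i}" for i in range(n_pairs)] + [f"R{i}" for i in range(n_pairs)]
        table = build_mismatch_table(
            make_matrix(calls, sample_ids=ids),
            make_cohort([(f"D{i}", f"R{i}") for i in range(n_pairs)]),
        )
        kept, _ = mismatch_frequency_filter(table, 0.30)
        # frequencies are j/10; kept iff j >= 3 -> variants 3..9
        assert kept == [f"var{j}" for j in range(3, 10)]


def _two_pair_table(raws=(10, 30), n_variants=40) -> MismatchTable:
    """Two pairs whose donor introduces ALT at the first `raw` variants."""
    donors = np.zeros((2, n_variants), dtype=np.int8)
    donors[0, : raws[0]] = 1
    donors[1, : raws[1]] = 1
    calls = np.vstack([donors, np.zeros((2, n_variants), dtype=np.int8)])
    ids = ["D0", "D1", "R0", "R1"]
    m = make_matrix(calls, sample_ids=ids)
    return build_mismatch_table(m, make_cohort([("D0", "R0"), ("D1", "R1")]))


class TestScores:
    def test_region_modes_hand_sum(self):
        # three variants with calls SINGLE, DOUBLE, NONE inside one region
        m = make_matrix([[1, 2, 0], [0, 0, 0]], sample_ids=["D", "R"], pos=[100, 200, 300])
        table = build_mismatch_table(m, make_cohort([("D", "R")]))
        regions = RegionAnnotation(
            pd.DataFrame(
                {"chrom": ["chr1"], "start": [0], "end": [400],
                 "region_id": ["g"], "region_class": ["gene"]}
            )
        )
        assert region_score(table, regions, "any")["g"].raw.tolist() == [2]
        assert region_score(table, regions, "double")["g"].raw.tolist() == [1]

    def test_empty_region_scores_zero(self):
        m = make_matrix([[1], [0]], sample_ids=["D", "R"], pos=[100])
        table = build_mismatch_table(m, make_cohort([("D", "R")]))
        regions = RegionAnnotation(
            pd.DataFrame(
                {"chrom": ["chr9"], "start": [0], "end": [50],
                 "region_id": ["empty"], "region_class": ["gene"]}
            )
        )
        assert region_score(table, regions)["empty"].raw.tolist() == [0]

    def test_overlapping_regions_both_count(self):
        m = make_matrix([[1], [0]], sample_ids=["D", "R"], pos=[100])
        table = build_mismatch_table(m, make_cohort([("D", "R")]))
        regions = RegionAnnotation(
            pd.DataFrame(
                {"chrom": ["chr1", "chr1"], "start": [0, 50], "end": [150, 200],
                 "region_id": ["g1", "g2"], "region_class": ["gene", "gene"]}
            )
        )
        raw = region_score_matrix(table, regions)
        assert raw["g1"].tolist() == [1] and raw["g2"].tolist() == [1]

    def test_genome_wide_normalization_follows_quantile_convention(self):
        table = _two_pair_table((10, 30))
        score = genome_wide_score(table)
        width = iqr(np.array([10, 30]))
        assert score.raw.tolist() == [10, 30]
        np.testing.assert_allclose(score.normalized, np.array([10, 30]) / width)

    def test_identical_pairs_zero_raw_and_normalization_error(self):
        donors = np.zeros((2, 10), dtype=np.int8)
        calls = np.vstack([donors, np.zeros((2, 10), dtype=np.int8)])
        m = make_matrix(calls, sample_ids=["D0", "D1", "R0", "R1"])
        table = build_mismatch_table(m, make_cohort([("D0", "R0"), ("D1", "R1")]))
        with pytest.raises(NormalizationError):
            genome_wide_score(table)

    def test_constant_shift_preserves_ranking(self):
        base = _two_pair_table((10, 30), n_variants=40)
        # add 5 universally mismatched variants
        shifted = _two_pair_table((15, 35), n_variants=40)
        r1 = genome_wide_score(base).raw
        r2 = genome_wide_score(shifted).raw
        assert np.array_equal(np.argsort(r1), np.argsort(r2))
        assert np.array_equal(r2 - r1, [5, 5])

    def test_iqr_normalization_is_positive_rescaling(self, rng):
        raw = rng.integers(0, 1000, size=50).astype(float)
        st_table = ScoreTable.from_raw("genome_wide", pd.RangeIndex(50), raw)
        order_raw = np.argsort(raw)
        order_norm = np.argsort(st_table.normalized)
        assert np.array_equal(order_raw, order_norm)

    def test_class_scores_partition_additivity(self, rng):
        n_pairs, n_var = 10, 60
        donors = rng.integers(0, 3, size=(n_pairs, n_var)).astype(np.int8)
        recips = rng.integers(0, 3, size=(n_pairs, n_var)).astype(np.int8)
        calls = np.vstack([donors, recips])
        ids = [f"D{i}" for i in range(n_pairs)] + [f"R{i}" for i in range(n_pairs)]
        table = build_mismatch_table(
            make_matrix(calls, sample_ids=ids),
            make_cohort([(f"D{i}", f"R{i}") for i in range(n_pairs)]),
        )
        labels = rng.choice(["exonic", "non_exonic", "transmembrane_nonsyn"], size=n_var)
        per_class, corr = class_scores(table, labels)
        total = sum(sc.raw for sc in per_class.values())
        np.testing.assert_array_equal(total, genome_wide_score(table).raw)
        assert corr.shape == (3, 3)

    def test_unknown_class_label_rejected(self):
        table = _two_pair_table()
        with pytest.raises(ValidationError):
            class_scores(table, np.array(["mystery"] * len(table.variants)))


class TestEstimatePibd:
    def test_self_is_one(self, rng):
        p = rng.uniform(0.1, 0.9, 6000)
        g = rng.binomial(2, p)
        est = estimate_pibd(g, g, p)
        assert est.pihat == pytest.approx(1.0, abs=0.05)

    def test_unrelated_is_zero(self, rng):
        p = rng.uniform(0.1, 0.9, 6000)
        g1, g2 = rng.binomial(2, p), rng.binomial(2, p)
        assert estimate_pibd(g1, g2, p).pihat == pytest.approx(0.0, abs=0.05)

    def test_parent_offspring_is_half(self, rng):
        p = rng.uniform(0.1, 0.9, 6000)
        shared = (rng.random(6000) < p).astype(int)
        g1 = shared + (rng.random(6000) < p)
        g2 = shared + (rng.random(6000) < p)
        assert estimate_pibd(g1, g2, p).pihat == pytest.approx(0.5, abs=0.05)

    def test_few_sites_flagged(self, rng):
        p = np.full(50, 0.5)
        g = rng.binomial(2, p)
        est = estimate_pibd(g, g, p)
        assert est.low_confidence
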