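"""Cox partial-likelihood fitting, log-rank, and the screening layer."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from drmatch.genotype_io import RegionAnnotation, ValidationError
from drmatch.mismatch import build_mismatch_table, genome_wide_score
from drmatch.survival import (
    CoxError,
    aggregate_gene_score,
    cohort_design,
    cox_score_test,
    dosage_trend,
    fit_cox,
    gene_screen,
    km_logrank,
    variant_screen,
)

from conftest import make_cohort, make_matrix


def oracle_partial_loglik(beta: float, time, event, x) -> float:
    """Written-out Cox partial likelihood for one covariate, no ties."""
    ll = 0.0
    for i in np.flatnonzero(event):
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def grid_search_beta(time, event, x) -> float:
    res = minimize_scalar(
        lambda b: -oracle_partial_loglik(b, time, event, x), bounds=(-8, 8), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


class TestFitCox:
    def test_identical_groups_null_effect(self):
        time = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        event = np.tile([1, 1, 0, 1], 2)
        group = np.repeat([0.0, 1.0], 4)
        fit = fit_cox(time, event, pd.DataFrame({"g": group}))
        assert fit.coefs["g"] == pytest.approx(0.0, abs=1e-8)
        assert fit.p_values["g"] == pytest.approx(1.0, abs=1e-6)

    def test_eight_subject_dataset_matches_grid_search(self):
        time = np.array([3.0, 5.0, 7.0, 2.0, 11.0, 13.0, 4.0, 9.0])
        event = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        fit = fit_cox(time, event, pd.DataFrame({"x": x}))
        assert fit.coefs["x"] == pytest.approx(grid_search_beta(time, event, x), abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_tiefree_microdatasets_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 11)
        time = rng.uniform(1, 100, n)  # continuous: no ties a.s.
        event = rng.integers(0, 2, n)
        if event.sum() == 0:
            event[0] = 1
        x = rng.normal(size=n)
        fit = fit_cox(time, event, pd.DataFrame({"x": x}))
        if fit.converged and abs(fit.coefs["x"]) < 7:
            assert fit.coefs["x"] == pytest.approx(grid_search_beta(time, event, x), abs=1e-6)

    def test_agrees_with_lifelines_including_ties(self, rng):
        from lifelines import CoxPHFitter

        n = 150
        x = pd.DataFrame({"a": rng.normal(size=n), "b": rng.integers(0, 2, n).astype(float)})
        t0 = rng.exponential(1 / np.exp(0.4 * x["a"]))
        time = np.ceil(np.minimum(t0, rng.exponential(2, n)) * 8)  # heavy ties
        event = (t0 <= rng.exponential(2, n)).astype(int)
        fit = fit_cox(time, event, x)
        df = x.assign(T=time, E=event)
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.coefs.to_numpy(), cph.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(
            fit.summary["se"].to_numpy(), cph.standard_errors_.to_numpy(), atol=1e-5
        )

    def test_stratified_single_stratum_equals_unstratified(self, rng):
        n = 80
        x = pd.DataFrame({"a": rng.normal(size=n)})
        time = rng.exponential(1, n)
        event = rng.integers(0, 2, n)
        event[0] = 1
        plain = fit_cox(time, event, x)
        strat = fit_cox(time, event, x, strata=np.zeros(n))
        assert plain.coefs["a"] == pytest.approx(strat.coefs["a"], abs=1e-10)

    def test_stratification_changes_fit_with_two_baselines(self, rng):
        n = 120
        strata = np.repeat([0, 1], n // 2)
        x = pd.DataFrame({"a": rng.normal(size=n)})
        time = rng.exponential(np.where(strata == 0, 1.0, 10.0))
        event = np.ones(n, dtype=int)
        plain = fit_cox(time, event, x)
        strat = fit_cox(time, event, x, strata=strata)
        assert strat.converged
        assert plain.coefs["a"] != pytest.approx(strat.coefs["a"], abs=1e-12)

    def test_no_events_rejected(self):
        with pytest.raises(CoxError):
            fit_cox(np.array([1.0, 2.0]), np.array([0, 0]), pd.DataFrame({"x": [0.0, 1.0]}))

    def test_rank_deficiency_names_columns(self, rng):
        n = 40
        a = rng.normal(size=n)
        with pytest.raises(CoxError, match="rank deficient"):
            fit_cox(
                rng.exponential(1, n),
                np.ones(n, dtype=int),
                pd.DataFrame({"a": a, "a_copy": a}),
            )

    def test_complete_separation_flagged_not_silent(self):
        # the covariate perfectly orders the event times: monotone likelihood
        time = np.arange(1.0, 11.0)
        event = np.ones(10, dtype=int)
        x = pd.DataFrame({"x": np.arange(10.0)})
        fit = fit_cox(time, event, x)
        assert (not fit.converged) or fit.warnings


class TestKmLogrank:
    def test_identical_groups_null(self):
        time = np.tile([1.0, 2, 3, 4, 5], 2)
        event = np.tile([1, 0, 1, 1, 0], 2)
        groups = np.repeat(["a", "b"], 5)
        _, chi2, p = km_logrank(time, event, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_six_subject_hand_worked_example(self):
        # A: 1+, 3+, 5c ; B: 2+, 4c, 6+  (+ event, c censored)
        time = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
        event = np.array([1, 1, 0, 1, 0, 1])
        groups = np.array(["A", "A", "A", "B", "B", "B"])
        # hand computation: O_A = 2, E_A = 3/6 + 2/5 + 2/4 = 1.4
        # hypergeometric variances: 0.25 + 0.24 + 0.25 + 0 = 0.74
        expected_chi2 = (2 - 1.4) ** 2 / 0.74
        _, chi2, _ = km_logrank(time, event, groups)
        assert chi2 == pytest.approx(expected_chi2, abs=1e-9)

    def test_km_without_censoring_is_empirical_survival(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.ones(4, dtype=int)
        curves, _, _ = km_logrank(
            np.r_[time, time], np.r_[event, event], np.repeat(["x", "y"], 4)
        )
        sf = curves["x"].set_index("time")["survival"]
        np.testing.assert_allclose(sf.loc[[1.0, 2.0, 3.0, 4.0]], [0.75, 0.5, 0.25, 0.0])

    def test_logrank_equals_cox_score_test(self, rng):
        n = 60
        time = rng.uniform(1, 100, n)  # tie-free
        event = rng.integers(0, 2, n)
        event[:5] = 1
        g = (rng.random(n) < 0.5).astype(float)
        chi2_score, _ = cox_score_test(time, event, pd.DataFrame({"g": g}))
        _, chi2_lr, _ = km_logrank(time, event, g)
        assert chi2_score == pytest.approx(chi2_lr, abs=1e-6)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            km_logrank(np.array([1.0, 2.0]), np.array([1, 1]), np.array(["a", "a"]))


# ---------------------------------------------------------------------------
# screening layer on a small constructed cohort
# ---------------------------------------------------------------------------


def small_screen_cohort(rng, n_pairs=120, n_genes=6, vpg=3):
    n_var = n_genes * vpg
    donors = rng.binomial(2, 0.4, size=(n_pairs, n_var)).astype(np.int8)
    recips = rng.binomial(2, 0.4, size=(n_pairs, n_var)).astype(np.int8)
    calls = np.vstack([donors, recips])
    ids = [f"D{i}" for i in range(n_pairs)] + [f"R{i}" for i in range(n_pairs)]
    m = make_matrix(calls, sample_ids=ids)
    time = rng.exponential(500, n_pairs) + 1
    event = (rng.random(n_pairs) < 0.3).astype(int)
    cohort = make_cohort(
        [(f"D{i}", f"R{i}") for i in range(n_pairs)],
        follow_time=list(time),
        event=list(event),
    )
    rows = []
    for g in range(n_genes):
        lo = 1000 * (g * vpg + 1) - 1
        hi = 1000 * ((g + 1) * vpg) + 1
        rows.append({"chrom": "chr1", "start": lo - 1, "end": hi,
                     "region_id": f"g{g}", "region_class": "gene"})
    regions = RegionAnnotation(pd.DataFrame(rows))
    table = build_mismatch_table(m, cohort)
    return table, regions, cohort


class TestScreens:
    def test_gene_screen_deterministic_under_gene_permutation(self, rng):
        table, regions, cohort = small_screen_cohort(rng)
        gw = genome_wide_score(table)
        subset = np.ones(cohort.n_pairs, dtype=bool)
        res1 = gene_screen(table, regions, cohort, gw, subset, threshold=0.5)
        shuffled = RegionAnnotation(regions.table.sample(frac=1, random_state=1))
        res2 = gene_screen(table, shuffled, cohort, gw, subset, threshold=0.5)
        a = res1.results.set_index(["unit", "scenario"]).sort_index()
        b = res2.results.set_index(["unit", "scenario"]).sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_intersection_requires_all_scenarios(self, rng):
        table, regions, cohort = small_screen_cohort(rng)
        gw = genome_wide_score(table)
        subset = np.ones(cohort.n_pairs, dtype=bool)
        res = gene_screen(table, regions, cohort, gw, subset, threshold=0.0)
        assert not res.intersection.any()  # threshold 0 -> empty intersection

    def test_aggregate_single_gene_equals_gene_score(self, rng):
        table, regions, cohort = small_screen_cohort(rng)
        from drmatch.mismatch import region_score_matrix

        raw = region_score_matrix(table, regions, "any")
        agg, _ = aggregate_gene_score(["g0"], table, regions)
        np.testing.assert_array_equal(agg.raw, raw["g0"].to_numpy())

    def test_aggregate_additivity_and_partition_identity(self, rng):
        table, regions, cohort = small_screen_cohort(rng)
        from drmatch.mismatch import region_score_matrix

        raw = region_score_matrix(table, regions, "any")
        agg, complement = aggregate_gene_score(["g0", "g3"], table, regions)
        np.testing.assert_array_equal(agg.raw, (raw["g0"] + raw["g3"]).to_numpy())
        # genes tile all variants -> aggregate of all + empty complement
        all_genes = list(regions.table["region_id"])
        agg_all, comp_all = aggregate_gene_score(all_genes, table, regions)
        np.testing.assert_array_equal(
            agg_all.raw + comp_all.raw - comp_all.raw, genome_wide_score(table).raw
        )
        assert (comp_all.raw == 0).all()

    def test_variant_screen_excludes_tag(self, rng):
        table, regions, cohort = small_screen_cohort(rng)
        ids = table.variants["variant_id"].tolist()[:5]
        tag_risk = rng.random(cohort.n_pairs) < 0.15
        res = variant_screen(
            ids, table, cohort, tag_risk, np.ones(cohort.n_pairs, bool),
            tag_variant=ids[0], threshold=0.5,
        )
        assert ids[0] not in set(res.results["unit"])

    def test_dosage_trend_all_one_level_rejected(self, rng):
        _, _, cohort = small_screen_cohort(rng)
        with pytest.raises(ValidationError):
            dosage_trend(np.zeros(cohort.n_pairs), cohort)

    def test_dosage_trend_recovers_positive_effect(self):
        rng = np.random.default_rng(7)
        n = 300
        dosage = rng.integers(0, 3, n).astype(float)
        lam = 0.002 * np.exp(0.6 * dosage)
        t0 = rng.exponential(1 / lam)
        time = np.minimum(t0, 1000.0)
        event = (t0 <= 1000.0).astype(int)
        cohort = make_cohort(
            [(f"D{i}", f"R{i}") for i in range(n)], follow_time=list(time), event=list(event)
        )
        fit, curves, chi2, p = dosage_trend(dosage, cohort)
        assert fit.summary.loc["dosage", "ci_lower"] < np.exp(0.6) < fit.summary.loc["dosage", "ci_upper"]
        assert p < 0.05
        assert set(curves) == {"0", "1", "2"}

    def test_cohort_design_encodes_categoricals(self, rng):
        _, _, cohort = small_screen_cohort(rng)
        design = cohort_design(cohort)
        assert "hla_mismatch" in design.columns
        assert "donor_living" in design.columns
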