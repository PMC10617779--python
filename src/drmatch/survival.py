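"""Survival association layer: Cox screening, Kaplan-Meier and log-rank.

The centerpiece is a compact Cox proportional-hazards fitter (Efron tie
handling by default, Breslow by flag, optional strata with separate
baseline hazards) maximizing the partial likelihood by Newton-Raphson with
step halving.  It exists in-package because the genome-wide gene screen
and locus variant screen refit the same small model thousands of times
with only the exposure column changing, a workload where per-fit overhead
dominates; lifelines is used for Kaplan-Meier curves and the log-rank test
and serves as an independent numerical cross-check of the fitter in the
test suite.

Screening follows the cohort-study design: gene-level mismatch scores are
tested one gene at a time in a multivariable model adjusting the
genome-wide mismatch score, the HLA mismatch score and clinical
covariates, under four scenarios (any/double mismatch x full
cohort/ancestry-homogeneous subset); a unit is flagged when it is
nominally significant in every scenario.  No multiplicity correction is
applied at the screen stage: the intersection across scenarios (plus
external validation) plays the role of error control in this design,
which is not the same thing as a calibrated multiple-testing procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import PairCohort, RegionAnnotation, ValidationError
from .mismatch import MismatchTable, ScoreTable, region_score_matrix

logger = logging.getLogger(__name__)


class CoxError(ValueError):
    pass


@dataclass
class CoxFit:
    """A converged (or flagged) proportional-hazards fit.

    ``summary`` is indexed by covariate name with columns
    ``coef, se, hr, z, p, ci_lower, ci_upper`` where ``hr = exp(coef)`` and
    the CI is ``exp(coef +/- 1.96 se)``.
    """

    summary: pd.DataFrame
    n: int
    n_events: int
    ties: str
    converged: bool
    log_likelihood: float
    warnings: list[str] = field(default_factory=list)

    @property
    def coefs(self) -> pd.Series:
        return self.summary["coef"]

    @property
    def hazard_ratios(self) -> pd.Series:
        return self.summary["hr"]

    @property
    def p_values(self) -> pd.Series:
        return self.summary["p"]


def _partial_loglik_gradient(
    beta: np.ndarray,
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, score and information for one stratum.

    Vectorized over tied-time groups: risk-set sums are reversed cumulative
    group sums, and the Efron within-tie corrections are expanded with
    ``np.repeat`` so no Python loop over event times remains.
    """
    order = np.argsort(time, kind="mergesort")
    x = x[order]
    time = time[order]
    event = event[order].astype(float)
    n, p = x.shape

    eta = x @ beta
    eta = eta - eta.max()  # guard overflow; partial likelihood is shift-invariant
    w = np.exp(eta)
    wx = w[:, None] * x
    wxx = wx[:, :, None] * x[:, None, :]

    starts = np.flatnonzero(np.r_[True, time[1:] != time[:-1]])
    # risk-set sums at each unique time (sum over all subjects with time >= t)
    s0 = np.add.reduceat(w, starts)[::-1].cumsum()[::-1]
    s1 = np.add.reduceat(wx, starts, axis=0)[::-1].cumsum(axis=0)[::-1]
    s2 = np.add.reduceat(wxx, starts, axis=0)[::-1].cumsum(axis=0)[::-1]
    # tie-group sums over events only
    d_g = np.add.reduceat(event, starts)
    sd0 = np.add.reduceat(w * event, starts)
    sd1 = np.add.reduceat(wx * event[:, None], starts, axis=0)
    sd2 = np.add.reduceat(wxx * event[:, None, None], starts, axis=0)

    has_events = d_g > 0
    d_int = d_g[has_events].astype(int)
    rep = np.repeat(np.flatnonzero(has_events), d_int)
    if ties == "breslow":
        frac = np.zeros(len(rep))
    else:
        frac = (np.arange(len(rep)) - np.repeat(np.r_[0, d_int[:-1]].cumsum(), d_int)) / np.repeat(
            d_int, d_int
        )

    den = s0[rep] - frac * sd0[rep]
    num1 = s1[rep] - frac[:, None] * sd1[rep]
    num2 = s2[rep] - frac[:, None, None] * sd2[rep]
    avg = num1 / den[:, None]

    ev_mask = event == 1
    loglik = float(eta[ev_mask].sum() - np.log(den).sum())
    score = x[ev_mask].sum(axis=0) - avg.sum(axis=0)
    info = (num2 / den[:, None, None]).sum(axis=0) - np.einsum("ri,rj->ij", avg, avg)
    return loglik, score, info


def fit_cox(
    time: np.ndarray | pd.Series,
    event: np.ndarray | pd.Series,
    covariates: pd.DataFrame,
    strata: np.ndarray | pd.Series | None = None,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Convergence is declared when the largest score component falls below
    ``tol`` (default 1e-8) within ``max_iter`` iterations.  Monotone
    likelihood (complete separation) and non-convergence are flagged on the
    returned fit rather than silently accepted.  ``strata`` gives each
    stratum its own baseline hazard.
    """
    if ties not in ("efron", "breslow"):
        raise ValidationError(f"unknown ties method {ties!r}")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not np.isin(event, (0, 1)).all():
        raise ValidationError("event must be 0/1")
    if (time <= 0).any():
        raise ValidationError("times must be positive")
    names = list(covariates.columns)
    x = covariates.to_numpy(dtype=float)
    n, p = x.shape
    n_events = int(event.sum())
    if n_events < 1:
        raise CoxError("no events; partial likelihood undefined")
    if np.linalg.matrix_rank(x) < p:
        corr = pd.DataFrame(x, columns=names).corr().abs()
        np.fill_diagonal(corr.to_numpy(), 0)
        worst = corr.stack().idxmax() if p > 1 else (names[0], names[0])
        raise CoxError(f"covariates are rank deficient (check {worst[0]!r} vs {worst[1]!r})")

    if strata is None:
        groups = [np.arange(n)]
    else:
        strata = np.asarray(strata)
        groups = [np.nonzero(strata == s)[0] for s in pd.unique(strata)]

    # center for numerical stability; slopes are invariant
    x_mean = x.mean(axis=0)
    xc = x - x_mean

    beta = np.zeros(p)
    warnings_: list[str] = []
    converged = False
    loglik = -np.inf
    for _ in range(max_iter):
        ll = 0.0
        score = np.zeros(p)
        info = np.zeros((p, p))
        for g in groups:
            if event[g].sum() == 0:
                continue
            l, s, i_ = _partial_loglik_gradient(beta, xc[g], time[g], event[g], ties)
            ll += l
            score += s
            info += i_
        if np.abs(score).max() < tol:
            loglik = ll
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            warnings_.append("singular information matrix")
            break
        # step halving if the likelihood would decrease
        new_beta = beta + step
        for _ in range(20):
            ll_new = sum(
                _partial_loglik_gradient(new_beta, xc[g], time[g], event[g], ties)[0]
                for g in groups
                if event[g].sum() > 0
            )
            if ll_new >= ll - 1e-12:
                break
            new_beta = (beta + new_beta) / 2
        beta = new_beta
        loglik = ll
        if np.abs(beta).max() > 200:
            warnings_.append("monotone likelihood / complete separation suspected")
            break
    else:
        warnings_.append(f"not converged in {max_iter} iterations")

    # final quantities at beta
    ll = 0.0
    info = np.zeros((p, p))
    for g in groups:
        if event[g].sum() == 0:
            continue
        l, _, i_ = _partial_loglik_gradient(beta, xc[g], time[g], event[g], ties)
        ll += l
        info += i_
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        warnings_.append("variance unavailable (singular information)")
    # a "converged" solution at an extreme coefficient is monotone likelihood
    if np.abs(beta).max() > 15:
        warnings_.append("extreme coefficient; monotone likelihood / separation suspected")
    z = np.divide(beta, se, out=np.full(p, np.nan), where=se > 0)
    pvals = 2 * stats.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):  # CI bounds may overflow on separated fits
        summary = pd.DataFrame(
            {
                "coef": beta,
                "se": se,
                "hr": np.exp(beta),
                "z": z,
                "p": pvals,
                "ci_lower": np.exp(beta - 1.96 * se),
                "ci_upper": np.exp(beta + 1.96 * se),
            },
            index=pd.Index(names, name="covariate"),
        )
    if warnings_:
        logger.warning("Cox fit flagged: %s", "; ".join(warnings_))
    return CoxFit(summary, n, n_events, ties, converged, float(ll), warnings_)


def cox_score_test(
    time: np.ndarray,
    event: np.ndarray,
    covariates: pd.DataFrame,
    ties: str = "breslow",
) -> tuple[float, float]:
    """Score (Rao) test at beta = 0; equals the log-rank test for group dummies."""
    x = covariates.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    _, score, info = _partial_loglik_gradient(
        np.zeros(x.shape[1]), x, np.asarray(time, float), np.asarray(event, int), ties
    )
    chi2 = float(score @ np.linalg.solve(info, score))
    p = float(stats.chi2.sf(chi2, x.shape[1]))
    return chi2, p


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------


def km_logrank(
    time: np.ndarray | pd.Series,
    event: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per group plus the k-group log-rank test.

    Returns ``(curves, chi2, p)`` where ``curves`` maps each group label to
    a DataFrame with columns ``time`` and ``survival``.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValidationError("log-rank needs at least 2 groups")
    curves: dict[str, pd.DataFrame] = {}
    for lab in labels:
        mask = groups == lab
        if mask.sum() == 0:
            raise ValidationError(f"group {lab!r} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[str(lab)] = sf
    res = multivariate_logrank_test(time, groups, event)
    return curves, float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

SCENARIOS_GENE = ["any/all", "double/all", "any/subset", "double/subset"]
SCENARIOS_VARIANT = ["adjusted/all", "stratified/all", "adjusted/subset", "stratified/subset"]


def cohort_design(cohort: PairCohort, genome_score: ScoreTable | None = None) -> pd.DataFrame:
    """Adjustment covariates: HLA mismatch, induction, donor status (+ score).

    Categorical covariates are dummy-coded (first level dropped); pairs
    with missing covariate values are dropped listwise by the caller via
    the returned frame's NaN pattern.
    """
    t = cohort.table
    design = pd.DataFrame(index=t.index)
    design["hla_mismatch"] = t["hla_mismatch"].astype(float)
    design["donor_living"] = (t["donor_status"] == "living").astype(float)
    induction = pd.get_dummies(t["induction"], prefix="induction", drop_first=True, dtype=float)
    design = pd.concat([design, induction], axis=1)
    if genome_score is not None:
        scores = genome_score.normalized if genome_score.normalized is not None else genome_score.raw
        design["genome_wide_score"] = np.asarray(scores, dtype=float)
    return design


@dataclass
class ScreenResult:
    """Long-format per-unit, per-scenario screen output with intersection flags."""

    results: pd.DataFrame  # unit, scenario, coef, hr, se, p, converged, note
    intersection: pd.Series  # unit -> bool (p <= threshold in every scenario)
    threshold: float

    def manhattan(self, positions: pd.DataFrame | None = None) -> pd.DataFrame:
        """Per-unit minimum p across scenarios as -log10, plus coordinates."""
        ok = self.results.dropna(subset=["p"])
        minp = ok.groupby("unit")["p"].min()
        out = pd.DataFrame({"unit": minp.index, "p_min": minp.to_numpy()})
        out["neg_log10_p"] = -np.log10(np.clip(out["p_min"], 1e-300, None))
        if positions is not None:
            out = out.merge(positions, on="unit", how="left")
        return out.sort_values("unit").reset_index(drop=True)


def _screen_units(
    exposures: dict[str, dict[str, np.ndarray]],
    scenario_frames: dict[str, tuple[np.ndarray, np.ndarray, pd.DataFrame, np.ndarray]],
    threshold: float,
    ties: str = "efron",
) -> ScreenResult:
    """Shared screening loop.

    ``exposures[scenario][unit]`` is the exposure vector over all pairs;
    ``scenario_frames[scenario] = (time, event, adjust_frame, row_mask)``.
    """
    rows = []
    for scenario, units in exposures.items():
        time, event, adjust, mask = scenario_frames[scenario]
        for unit, expo in units.items():
            e = np.asarray(expo, dtype=float)[mask]
            note = ""
            if np.nanstd(e) == 0:
                rows.append(
                    dict(unit=unit, scenario=scenario, coef=np.nan, hr=np.nan, se=np.nan,
                         p=np.nan, converged=False, note="degenerate exposure")
                )
                continue
            design = adjust.copy()
            design.insert(0, "exposure", e)
            try:
                fit = fit_cox(time, event, design, ties=ties)
                row = fit.summary.loc["exposure"]
                if not fit.converged:
                    note = ";".join(fit.warnings)
                rows.append(
                    dict(unit=unit, scenario=scenario, coef=row["coef"], hr=row["hr"],
                         se=row["se"], p=row["p"], converged=fit.converged, note=note)
                )
            except (CoxError, ValidationError) as exc:
                rows.append(
                    dict(unit=unit, scenario=scenario, coef=np.nan, hr=np.nan, se=np.nan,
                         p=np.nan, converged=False, note=str(exc))
                )
    results = pd.DataFrame(rows)
    flags = (
        results.assign(hit=lambda d: d["p"] <= threshold)
        .groupby("unit")["hit"]
        .agg(lambda s: bool(s.all()) and s.notna().all())
    )
    return ScreenResult(results, flags, threshold)


def gene_screen(
    table_filtered: MismatchTable,
    regions: RegionAnnotation,
    cohort: PairCohort,
    genome_score: ScoreTable,
    subset_mask: np.ndarray,
    threshold: float = 0.05,
    ties: str = "efron",
) -> ScreenResult:
    """Four-scenario genome-wide gene-level mismatch screen.

    For each gene, the raw gene mismatch count (any- or double-mismatch
    indicator summed over the gene's variants, low-mismatch-frequency
    variants removed upstream) is the exposure in a Cox model adjusting the
    normalized genome-wide score, HLA mismatch, induction and donor status.
    Scenarios cross the mismatch definition (any/double) with the cohort
    (all pairs / ``subset_mask``, e.g. European-to-European pairs).  A gene
    is flagged when nominally significant in all four scenarios.
    """
    gene_regions = regions.of_class("gene") if "gene" in set(regions.table["region_class"]) else regions
    raw_any = region_score_matrix(table_filtered, gene_regions, "any")
    raw_double = region_score_matrix(table_filtered, gene_regions, "double")

    t = cohort.table
    adjust_all = cohort_design(cohort, genome_score)
    time = t["follow_time"].to_numpy(dtype=float)
    event = t["event"].to_numpy(dtype=int)
    subset_mask = np.asarray(subset_mask, dtype=bool)

    def frame(mask: np.ndarray):
        adj = adjust_all.loc[mask].reset_index(drop=True)
        adj = adj.loc[:, adj.std() > 0]  # drop constants within the subset
        return time[mask], event[mask], adj, mask

    # listwise deletion of pairs with missing covariates
    complete = adjust_all.notna().all(axis=1).to_numpy()
    if not complete.all():
        logger.info("gene_screen: dropping %d pair(s) with missing covariates", (~complete).sum())
    all_mask = complete
    scenario_frames = {
        "any/all": frame(all_mask),
        "double/all": frame(all_mask),
        "any/subset": frame(subset_mask & complete),
        "double/subset": frame(subset_mask & complete),
    }
    exposures = {
        "any/all": {g: raw_any[g].to_numpy() for g in raw_any.columns},
        "double/all": {g: raw_double[g].to_numpy() for g in raw_double.columns},
        "any/subset": {g: raw_any[g].to_numpy() for g in raw_any.columns},
        "double/subset": {g: raw_double[g].to_numpy() for g in raw_double.columns},
    }
    return _screen_units(exposures, scenario_frames, threshold, ties)


def aggregate_gene_score(
    gene_ids: list[str],
    table: MismatchTable,
    regions: RegionAnnotation,
    mode: str = "any",
) -> tuple[ScoreTable, ScoreTable]:
    """Sum gene-level raw scores over a candidate list, plus the complement.

    The aggregate is the sum of per-gene raw scores (a variant shared by two
    listed genes counts twice, consistent with per-gene scoring); the
    complement score covers every variant outside the union of the listed
    gene intervals, for the paired "remaining genome" comparison.
    """
    gene_regions = regions.of_class("gene") if "gene" in set(regions.table["region_class"]) else regions
    sel = gene_regions.table["region_id"].isin(gene_ids)
    if sel.sum() != len(set(gene_ids)):
        missing = set(gene_ids) - set(gene_regions.table["region_id"])
        raise ValidationError(f"genes absent from annotation: {sorted(missing)}")
    listed = RegionAnnotation(gene_regions.table[sel])
    raw = region_score_matrix(table, listed, mode)
    agg = raw.sum(axis=1).to_numpy()
    member = listed.variant_membership(table.variants).to_numpy().any(axis=1)
    complement = table.indicator(mode)[:, ~member].sum(axis=1)
    idx = pd.RangeIndex(table.cohort.n_pairs)
    return (
        ScoreTable.from_raw("class:aggregate", idx, agg, normalize=False),
        ScoreTable.from_raw("class:complement", idx, complement, normalize=False),
    )


def variant_screen(
    variant_ids: list[str],
    table: MismatchTable,
    cohort: PairCohort,
    tag_risk: np.ndarray,
    subset_mask: np.ndarray,
    adjust: pd.DataFrame | None = None,
    tag_variant: str | None = None,
    threshold: float = 0.05,
    ties: str = "efron",
) -> ScreenResult:
    """Variant-level locus screen independent of the tag-SNP risk mismatch.

    Each variant's any-mismatch indicator is tested (a) adjusted by the
    tag-risk indicator on all pairs and (b) within the tag-non-risk stratum
    (tag-risk pairs excluded), each in the full cohort and in
    ``subset_mask``.  Variants nominally significant in all four scenarios
    are candidate haplotype-block seeds.  The tag variant itself is
    excluded from its own screen.
    """
    tag_risk = np.asarray(tag_risk, dtype=bool)
    subset_mask = np.asarray(subset_mask, dtype=bool)
    ids = [v for v in variant_ids if v != tag_variant]
    sub = table.subset_variants(ids)
    any_ind = pd.DataFrame(
        sub.any_mismatch, columns=sub.variants["variant_id"].to_numpy()
    )

    t = cohort.table
    time = t["follow_time"].to_numpy(dtype=float)
    event = t["event"].to_numpy(dtype=int)
    base_adjust = adjust if adjust is not None else cohort_design(cohort)

    def frame(mask: np.ndarray, with_tag: bool):
        adj = base_adjust.loc[mask].reset_index(drop=True)
        if with_tag:
            adj = adj.copy()
            adj["tag_risk"] = tag_risk[mask].astype(float)
        adj = adj.loc[:, adj.std() > 0]
        return time[mask], event[mask], adj, mask

    complete = base_adjust.notna().all(axis=1).to_numpy()
    all_mask = complete
    subset_mask = subset_mask & complete
    scenario_frames = {
        "adjusted/all": frame(all_mask, with_tag=True),
        "stratified/all": frame(all_mask & ~tag_risk, with_tag=False),
        "adjusted/subset": frame(subset_mask, with_tag=True),
        "stratified/subset": frame(subset_mask & ~tag_risk, with_tag=False),
    }
    cols = {v: any_ind[v].to_numpy() for v in any_ind.columns}
    exposures = {s: cols for s in SCENARIOS_VARIANT}
    return _screen_units(exposures, scenario_frames, threshold, ties)


def dosage_trend(
    n_alien: np.ndarray,
    cohort: PairCohort,
    adjust: pd.DataFrame | None = None,
    ties: str = "efron",
) -> tuple[CoxFit, dict[str, pd.DataFrame], float, float]:
    """Haplotype mismatch-dosage effect: Cox trend plus KM curves by dosage.

    ``n_alien`` is the per-pair count of haplotype alleles introduced by
    the donor (0, 1 or 2).  Returns the Cox fit with dosage as a numeric
    exposure, the per-dosage Kaplan-Meier curves, and the log-rank
    chi-square and p-value.
    """
    n_alien = np.asarray(n_alien, dtype=float)
    if len(np.unique(n_alien)) < 2:
        raise ValidationError("all pairs share one mismatch dosage; trend undefined")
    t = cohort.table
    design = pd.DataFrame({"dosage": n_alien})
    if adjust is not None:
        design = pd.concat([design, adjust.reset_index(drop=True)], axis=1)
    fit = fit_cox(t["follow_time"], t["event"], design, ties=ties)
    curves, chi2, p = km_logrank(t["follow_time"], t["event"], n_alien.astype(int))
    return fit, curves, chi2, p
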