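"""Case/reference and symptom-level association statistics.

Three layers: (1) a two-sample t-test on standardized scores (pooled
variance by default, Welch optional); (2) logistic regression of case
status on the standardized score, reported as an odds ratio per SD with a
95% Wald confidence interval; (3) per-symptom one-way ANOVA comparing the
mean score of symptom-positive vs symptom-negative subjects, at a nominal
0.05 without multiple-testing correction by default (a Bonferroni option
exists).  All tests are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from prspipe.io import PhenotypeTable
from prspipe.scoring import ScoreSet

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class AssociationError(ValueError):
    pass


@dataclass(frozen=True)
class AssociationResult:
    """t-test and logistic OR-per-SD summary for one (trait, threshold)."""

    trait_label: str
    threshold: float | None
    delta: float  # mean std-score difference, cases - reference, SD units
    t_stat: float
    t_p: float
    or_per_sd: float
    ci_low: float
    ci_high: float
    wald_p: float
    n_case: int
    n_control: int
    n_snps: int | None = None
    status: str = "ok"  # ok | separation | no_convergence


@dataclass(frozen=True)
class SymptomAssociation:
    symptom: str
    domain: str
    n_yes: int
    n_no: int
    mean_prs_yes: float
    mean_prs_no: float
    f_stat: float
    p_value: float
    status: str = "ok"  # ok | untestable


def _as_bool_labels(labels, n: int) -> np.ndarray:
    arr = np.asarray(getattr(labels, "is_case", labels)).astype(bool)
    if arr.shape != (n,):
        raise AssociationError(f"labels length {arr.shape} does not match {n} samples")
    return arr


def ttest_case_control(
    scores: ScoreSet, labels, equal_var: bool = True
) -> tuple[float, float, float]:
    """Two-sample t-test of case vs reference mean score.

    Returns ``(delta, t_stat, p)`` where delta = mean(case) - mean(reference)
    on the standardized scale.  Pooled-variance by default; ``equal_var=False``
    selects Welch.  Each group must have at least 2 samples.
    """
    is_case = _as_bool_labels(labels, scores.n_samples)
    x = scores.values
    case, ref = x[is_case], x[~is_case]
    if len(case) < 2 or len(ref) < 2:
        raise AssociationError(
            f"t-test needs >=2 samples per group (got {len(case)} cases, {len(ref)} reference)"
        )
    delta = float(case.mean() - ref.mean())
    t_stat, p = stats.ttest_ind(case, ref, equal_var=equal_var)
    return delta, float(t_stat), float(p)


def logistic_or_per_sd(scores: ScoreSet, labels, equal_var: bool = True) -> AssociationResult:
    """Odds ratio per SD of score from a single-covariate logistic fit.

    Maximum-likelihood logistic regression of case status on the score with
    an intercept; OR = exp(slope), 95% CI = exp(slope +/- 1.96*SE), Wald P.
    Complete separation or non-convergence yields a flagged result (status
    ``separation`` / ``no_convergence``) with NaN interval rather than a
    fabricated one.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    is_case = _as_bool_labels(labels, scores.n_samples)
    if is_case.all() or not is_case.any():
        raise AssociationError("both outcome classes must be present")
    x = scores.values
    delta, t_stat, t_p = ttest_case_control(scores, is_case, equal_var=equal_var)
    X = sm.add_constant(x)

    status = "ok"
    beta = se = np.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(is_case.astype(float), X).fit(disp=False, maxiter=100)
        if not fit.mle_retvals.get("converged", False):
            status = "no_convergence"
        beta = float(fit.params[1])
        se = float(fit.bse[1])
        if not np.isfinite(se) or se > 1e3:
            status = "separation"
    except (PerfectSeparationError, np.linalg.LinAlgError):
        status = "separation"

    if status == "ok":
        or_per_sd = float(np.exp(beta))
        ci_low = float(np.exp(beta - Z_95 * se))
        ci_high = float(np.exp(beta + Z_95 * se))
        wald_p = float(2 * stats.norm.sf(abs(beta / se)))
    else:
        or_per_sd = float(np.exp(beta)) if np.isfinite(beta) else np.nan
        ci_low = ci_high = wald_p = np.nan

    return AssociationResult(
        trait_label=scores.trait_label,
        threshold=scores.threshold,
        delta=delta,
        t_stat=t_stat,
        t_p=t_p,
        or_per_sd=or_per_sd,
        ci_low=ci_low,
        ci_high=ci_high,
        wald_p=wald_p,
        n_case=int(is_case.sum()),
        n_control=int((~is_case).sum()),
        n_snps=scores.n_snps_included,
        status=status,
    )


def association_grid(score_grid, labels, equal_var: bool = True) -> list[AssociationResult]:
    """Run the t-test + logistic layer over every score-grid cell."""
    return [logistic_or_per_sd(s, labels, equal_var=equal_var) for s in score_grid]


def symptom_association(
    scores: ScoreSet,
    phenotypes: PhenotypeTable,
    bonferroni: bool = False,
) -> list[SymptomAssociation]:
    """Per-symptom one-way ANOVA of score by symptom status.

    Subjects are matched to scores by ID; missing symptom values are
    excluded pairwise.  A symptom observed at a single level is returned
    with status ``untestable`` instead of raising.  P-values are nominal
    unless ``bonferroni=True`` multiplies them by the number of testable
    symptoms (capped at 1).
    """
    pos = {sid: i for i, sid in enumerate(scores.sample_ids)}
    missing = [s for s in phenotypes.subject_ids if s not in pos]
    if missing:
        raise AssociationError(f"subjects without scores: {missing[:5]}")
    idx = np.array([pos[s] for s in phenotypes.subject_ids])
    x = scores.values[idx]

    results: list[SymptomAssociation] = []
    for symptom in phenotypes.symptoms:
        y = phenotypes.data[symptom].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        yes, no = x[ok & (y == 1)], x[ok & (y == 0)]
        base = dict(
            symptom=symptom,
            domain=phenotypes.domains[symptom],
            n_yes=len(yes),
            n_no=len(no),
            mean_prs_yes=float(yes.mean()) if len(yes) else np.nan,
            mean_prs_no=float(no.mean()) if len(no) else np.nan,
        )
        if len(yes) == 0 or len(no) == 0 or len(yes) + len(no) < 3:
            results.append(SymptomAssociation(**base, f_stat=np.nan, p_value=np.nan, status="untestable"))
            continue
        f_stat, p = stats.f_oneway(yes, no)
        results.append(SymptomAssociation(**base, f_stat=float(f_stat), p_value=float(p)))

    if bonferroni:
        m = sum(1 for r in results if r.status == "ok")
        results = [
            SymptomAssociation(
                **{**r.__dict__, "p_value": min(r.p_value * m, 1.0) if r.status == "ok" else r.p_value}
            )
            for r in results
        ]
    return results


def symptom_table(results: Sequence[SymptomAssociation]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def summarize_phenotypes(phenotypes: PhenotypeTable) -> pd.DataFrame:
    """Prevalence of each symptom, grouped by domain.

    Percentages use the non-missing denominator; ``denominator_differs``
    flags symptoms whose response count falls short of the cohort size
    (e.g. a printed 33.3% for 6 positives implies 18 respondents of 19).
    """
    n_total = len(phenotypes.subject_ids)
    if n_total == 0:
        raise AssociationError("empty phenotype table")
    rows = []
    for symptom in phenotypes.symptoms:
        y = phenotypes.data[symptom]
        n_obs = int(y.notna().sum())
        n_pos = int((y == 1).sum())
        rows.append(
            {
                "domain": phenotypes.domains[symptom],
                "symptom": symptom,
                "n_positive": n_pos,
                "n_responded": n_obs,
                "percent": 100.0 * n_pos / n_obs if n_obs else np.nan,
                "denominator_differs": n_obs != n_total,
            }
        )
    out = pd.DataFrame(rows)
    domain_order = {d: i for i, d in enumerate(dict.fromkeys(phenotypes.domains.values()))}
    return (
        out.sort_values("domain", key=lambda s: s.map(domain_order), kind="mergesort")
        .reset_index(drop=True)
    )
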