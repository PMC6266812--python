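"""Synthetic study generator: GWAS summary statistics, case/reference
genotype cohorts with a calibrated score shift, and follow-up symptom tables.

The generator emulates a small cross-trait PRS study: a handful of
trait-specific GWAS summary-statistic sets over a shared variant panel, a
22-case / 307-reference imputed-dosage cohort in which cases carry a
target standardized PRS shift delta, and a 19-subject prospective table of
binary symptoms in four allergic-disorder domains.

Case enrichment is realized retrospectively by tilting effect-allele
frequencies: for variants entering the score, case frequency is

    f'_j = clip(f_j + lambda * w_j * f_j (1 - f_j), eps, 1 - eps)

with a single scalar ``lambda`` solved in closed form so the expected raw
score difference equals ``delta_target`` times the raw-score SD under
independence.  Genotypes are drawn Binomial(2, f) per variant with no
linkage disequilibrium — independence is what makes the calibration exact
and matches the additive scoring model.

Every operation is a pure function of its inputs and the seed: identical
configuration and seed reproduce identical output, byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from prspipe.io import (
    SYMPTOM_DOMAINS,
    GenotypeMatrix,
    PhenotypeTable,
    SummaryStatSet,
    write_genotypes_vcf,
    write_phenotypes,
    write_summary_stats,
)
from prspipe.scoring import ScoreSet, select_snps

#: Frequency clipping bound keeping Binomial parameters valid.
FREQ_EPS = 1e-4

_BASES = np.array(list("ACGT"))

#: Follow-up symptom base rates mirroring the observed six-year prevalences
#: in the 19-subject cohort (counts out of 19).
DEFAULT_BASE_RATES = {
    "wheezing": 4 / 19,
    "dyspnoea": 4 / 19,
    "coughing_at_night": 5 / 19,
    "asthma_diagnosed": 6 / 19,
    "asthma_medication": 6 / 19,
    "irritated_nasal_mucosa": 6 / 19,
    "irritated_eyes": 3 / 19,
    "rhinitis_diagnosed": 1 / 19,
    "rhinitis_medication": 5 / 19,
    "eczema": 7 / 19,
    "topical_steroids": 6 / 19,
    "food_allergy": 3 / 19,
}

#: Default symptom effects (log-odds per SD of score): asthma-related
#: symptoms load positively on the score, mirroring the observed pattern of
#: higher mean scores in symptom-positive subjects; other domains are null.
DEFAULT_SYMPTOM_EFFECTS = {
    s: (1.0 if d == "asthma" else 0.0) for s, d in SYMPTOM_DOMAINS.items()
}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    Defaults emulate the study conditions: 22 cases vs 307 reference
    subjects; a standardized case score shift of 0.41 SD.  The variant
    panel (2000 SNPs) is a desk-scale stand-in for the millions of imputed
    variants of a real cohort; ``n_gwas`` = 50,000 reflects discovery GWAS
    of the era; 10% of variants causal with per-allele log-odds effects of
    SD 0.05 gives the summary statistics a realistic polygenic tail.
    """

    n_snps: int = 2000
    n_cases: int = 22
    n_controls: int = 307
    n_gwas: int = 50_000
    causal_fraction: float = 0.1
    effect_sd: float = 0.05
    maf_range: tuple[float, float] = (0.05, 0.5)
    delta_target: float = 0.41
    missing_rate: float = 0.01
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_snps, self.n_cases, self.n_controls, self.n_gwas) < 1:
            raise SimulationError("n_snps, n_cases, n_controls, n_gwas must all be >= 1")
        if not 0 <= self.causal_fraction <= 1:
            raise SimulationError("causal_fraction must lie in [0, 1]")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise SimulationError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0 <= self.missing_rate < 1:
            raise SimulationError("missing_rate must lie in [0, 1)")
        if self.effect_sd < 0:
            raise SimulationError("effect_sd must be non-negative")


@dataclass(frozen=True)
class FrequencyShift:
    """Per-variant case allele frequencies realizing a target score shift.

    ``lambda_`` is the scalar tilt; ``case_freq`` is indexed by variant ID
    and equals the control frequency for variants outside the score.
    ``lambda_`` = 0 implies case frequencies identical to control ones.
    """

    lambda_: float
    case_freq: pd.Series
    n_clipped: int = 0
    delta_target: float = 0.0


@dataclass(frozen=True)
class CohortLabels:
    sample_ids: list[str]
    is_case: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "is_case", np.asarray(self.is_case, dtype=bool))

    @property
    def n_case(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_control(self) -> int:
        return int((~self.is_case).sum())


def _panel(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Shared variant panel: IDs, positions, alleles, control frequencies."""
    m = config.n_snps
    chrom = rng.integers(1, 23, size=m)
    pos = rng.integers(1, 250_000_000, size=m)
    ea_idx = rng.integers(0, 4, size=m)
    oa_idx = (ea_idx + rng.integers(1, 4, size=m)) % 4  # distinct; includes A/T, C/G pairs
    lo, hi = config.maf_range
    freq = rng.uniform(lo, hi, size=m)
    panel = pd.DataFrame(
        {
            "id": [f"rs{i + 1:07d}" for i in range(m)],
            "chrom": chrom.astype(str),
            "pos": pos,
            "effect_allele": _BASES[ea_idx],
            "other_allele": _BASES[oa_idx],
            "effect_allele_freq": freq,
        }
    )
    return panel.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def simulate_summary_stats(
    config: SimulationConfig,
    trait_label: str = "trait",
    panel: pd.DataFrame | None = None,
    seed: int | None = None,
) -> SummaryStatSet:
    """Fabricate one trait's GWAS summary statistics.

    A fraction ``causal_fraction`` of variants receives a true per-allele
    effect ~ Normal(0, effect_sd^2) on the log-odds scale, the rest zero.
    The reported effect adds estimation noise with the standard-error
    formula of a marginal regression, ``se = 1 / sqrt(2 f (1-f) n_gwas)``,
    and the reported P-value is the two-sided normal tail of effect / se —
    so with no causal variants the P-values are marginally Uniform(0, 1).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if panel is None:
        panel = _panel(config, rng)
    f = panel["effect_allele_freq"].to_numpy()
    m = len(panel)
    causal = rng.random(m) < config.causal_fraction
    true_beta = np.where(causal, rng.normal(0.0, config.effect_sd, size=m), 0.0)
    se = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * config.n_gwas)
    beta_hat = true_beta + rng.normal(0.0, 1.0, size=m) * se
    p = 2.0 * stats.norm.sf(np.abs(beta_hat / se))
    p = np.clip(p, np.finfo(float).tiny, 1.0)  # keep P in (0, 1]

    table = panel.assign(weight=beta_hat, p_value=p)[
        ["id", "chrom", "pos", "effect_allele", "other_allele",
         "weight", "p_value", "effect_allele_freq"]
    ]
    return SummaryStatSet(trait_label=trait_label, table=table)


def calibrate_frequency_shift(
    sumstats: SummaryStatSet,
    threshold: float,
    delta_target: float,
    eps: float = FREQ_EPS,
) -> FrequencyShift:
    """Solve the frequency tilt that yields a target standardized shift.

    For variants with P < threshold, the expected raw score difference
    between cases and controls under the tilt is
    ``sum_j w_j * 2 (f'_j - f_j) = lambda * 2 * sum_j w_j^2 f_j (1 - f_j)``
    (before clipping), while the raw-score SD under independent
    Binomial(2, f) genotypes is ``sqrt(sum_j w_j^2 * 2 f_j (1 - f_j))``.
    Setting the two proportional gives the closed form

        lambda = delta_target / sqrt(2 * sum_j w_j^2 f_j (1 - f_j)).

    Clipping to [eps, 1 - eps] keeps Binomial parameters valid; the number
    of clipped frequencies is recorded on the result.
    """
    if not np.isfinite(delta_target):
        raise SimulationError("delta_target must be finite")
    included = select_snps(sumstats, threshold).table
    if included.empty:
        raise SimulationError(f"no variants pass threshold {threshold}")
    w = included["weight"].to_numpy()
    f = included["effect_allele_freq"].to_numpy()
    s2 = float(np.sum(w**2 * 2.0 * f * (1.0 - f)))
    if s2 == 0:
        raise SimulationError("all included weights are zero: no solvable tilt")
    lam = delta_target / np.sqrt(s2)

    case_freq = sumstats.table.set_index("id")["effect_allele_freq"].copy()
    tilted = f + lam * w * f * (1.0 - f)
    clipped = np.clip(tilted, eps, 1.0 - eps)
    n_clipped = int(np.sum(tilted != clipped))
    case_freq.loc[included["id"].to_numpy()] = clipped
    return FrequencyShift(
        lambda_=float(lam), case_freq=case_freq, n_clipped=n_clipped, delta_target=delta_target
    )


def simulate_cohort_genotypes(
    sumstats: SummaryStatSet,
    shift: FrequencyShift,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, CohortLabels]:
    """Draw case/reference genotype dosages for the summary-stat panel.

    Reference genotypes are Binomial(2, f_j); cases use the tilted
    frequencies f'_j.  Variants are independent (no LD).  About 30% of
    variants are stored with REF = effect allele (dosage on the ALT = other
    allele), so allele harmonization is exercised end to end.  Missing
    genotypes are introduced uniformly at ``missing_rate``; INFO scores are
    drawn Uniform(0.5, 1] so the INFO > 0.9 filter has both outcomes.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    t = sumstats.table
    if not t["id"].isin(shift.case_freq.index).all():
        raise SimulationError("shift was not derived from these summary statistics")
    f = t["effect_allele_freq"].to_numpy()
    f_case = shift.case_freq.loc[t["id"]].to_numpy()
    n_case, n_ctrl, m = config.n_cases, config.n_controls, len(t)

    eff_count = np.empty((n_case + n_ctrl, m), dtype=float)
    eff_count[:n_case] = rng.binomial(2, f_case, size=(n_case, m))
    eff_count[n_case:] = rng.binomial(2, f, size=(n_ctrl, m))

    if config.missing_rate > 0:
        eff_count[rng.random(eff_count.shape) < config.missing_rate] = np.nan

    swap = rng.random(m) < 0.3  # effect allele stored as REF for these
    dosage = np.where(swap, 2.0 - eff_count, eff_count)
    ref = np.where(swap, t["effect_allele"], t["other_allele"])
    alt = np.where(swap, t["other_allele"], t["effect_allele"])
    info = 1.0 - rng.uniform(0.0, 0.5, size=m)  # Uniform(0.5, 1]

    sample_ids = [f"case{i + 1:03d}" for i in range(n_case)] + [
        f"ctrl{i + 1:03d}" for i in range(n_ctrl)
    ]
    variants = pd.DataFrame(
        {
            "id": t["id"],
            "chrom": t["chrom"],
            "pos": t["pos"],
            "ref": ref,
            "alt": alt,
            "info_score": info,
        }
    )
    from prspipe.io import _maf_from_dosage

    variants["maf"] = _maf_from_dosage(dosage)
    labels = CohortLabels(
        sample_ids=sample_ids,
        is_case=np.arange(n_case + n_ctrl) < n_case,
    )
    matrix = GenotypeMatrix(sample_ids=sample_ids, variants=variants, dosage=dosage)
    return matrix, labels


def simulate_score_cohort(
    delta: float, n_case: int, n_control: int, seed: int
) -> tuple[ScoreSet, CohortLabels]:
    """Score-level shortcut for testing the association layer in isolation.

    Reference scores ~ Normal(0, 1), case scores ~ Normal(delta, 1),
    returned unstandardized (the association layer may restandardize).
    """
    if n_case < 1 or n_control < 1:
        raise SimulationError("need at least one sample per group")
    rng = np.random.default_rng(seed)
    raw = np.concatenate(
        [rng.normal(delta, 1.0, size=n_case), rng.normal(0.0, 1.0, size=n_control)]
    )
    sample_ids = [f"case{i + 1:03d}" for i in range(n_case)] + [
        f"ctrl{i + 1:03d}" for i in range(n_control)
    ]
    scores = ScoreSet(
        sample_ids=sample_ids,
        raw_score=raw,
        trait_label="simulated",
        threshold=None,
        n_snps_included=None,
    )
    labels = CohortLabels(
        sample_ids=sample_ids, is_case=np.arange(n_case + n_control) < n_case
    )
    return scores, labels


def simulate_followup_phenotypes(
    scores: ScoreSet,
    symptom_effects: Mapping[str, float] | None = None,
    base_rates: Mapping[str, float] | None = None,
    seed: int = 0,
    domains: Mapping[str, str] | None = None,
) -> PhenotypeTable:
    """Binary symptom outcomes driven by the score.

    Each symptom j for subject i is Bernoulli with
    ``logistic(logit(base_rate_j) + effect_j * score_i)``, so with all
    effects zero the prevalence equals the base rate and a positive effect
    raises the mean score among symptom-positive subjects.
    """
    effects = dict(DEFAULT_SYMPTOM_EFFECTS if symptom_effects is None else symptom_effects)
    rates = dict(DEFAULT_BASE_RATES if base_rates is None else base_rates)
    if set(effects) != set(rates):
        raise SimulationError("symptom_effects and base_rates must cover the same symptoms")
    bad = {s: r for s, r in rates.items() if not 0 < r < 1}
    if bad:
        raise SimulationError(f"base rates must lie in (0, 1): {bad}")
    domain_of = dict(SYMPTOM_DOMAINS)
    if domains:
        domain_of.update(domains)
    missing_domain = [s for s in effects if s not in domain_of]
    if missing_domain:
        raise SimulationError(f"symptoms without a domain: {missing_domain}")

    rng = np.random.default_rng(seed)
    x = scores.values
    data = {}
    for symptom in effects:
        eta = np.log(rates[symptom] / (1.0 - rates[symptom])) + effects[symptom] * x
        prob = 1.0 / (1.0 + np.exp(-eta))
        data[symptom] = (rng.random(len(x)) < prob).astype(float)
    return PhenotypeTable(
        subject_ids=list(scores.sample_ids),
        data=pd.DataFrame(data),
        domains={s: domain_of[s] for s in effects},
    )


DEFAULT_TRAITS = ("asthma", "asd", "atopic_dermatitis", "ibd", "rheumatoid_arthritis")


@dataclass
class StudyData:
    """A complete synthetic study: sumstats per trait, cohort, follow-up."""

    sumstats: dict[str, SummaryStatSet]
    matrix: GenotypeMatrix
    labels: CohortLabels
    phenotypes: PhenotypeTable
    shift: FrequencyShift
    config: SimulationConfig = field(default=None)


def simulate_study(
    config: SimulationConfig,
    traits: Sequence[str] = DEFAULT_TRAITS,
    shift_trait: str = "asthma",
    shift_threshold: float = 0.01,
    outdir: str | Path | None = None,
) -> StudyData:
    """Generate the full synthetic study, optionally writing pipeline inputs.

    All traits share one variant panel (as real cohorts share one genotyped
    panel) but have independent effects and P-values.  Case enrichment is
    calibrated on ``shift_trait`` at ``shift_threshold``; the other traits'
    scores are unshifted in expectation because their weights are
    independent of the tilt.  Follow-up phenotypes cover the first 19 cases
    (or all cases if fewer), driven by the shifted trait's score at the
    smallest grid threshold with any variants.

    With ``outdir`` set, writes ``<trait>_sumstats.tsv`` per trait,
    ``genotypes.vcf`` and ``phenotypes.csv``.
    """
    if shift_trait not in traits:
        raise SimulationError(f"shift_trait {shift_trait!r} not in traits {traits}")
    root = np.random.default_rng(config.seed)
    panel_rng = np.random.default_rng(root.integers(2**31 - 1))
    panel = _panel(config, panel_rng)
    sumstats = {
        trait: simulate_summary_stats(
            config, trait_label=trait, panel=panel, seed=int(root.integers(2**31 - 1))
        )
        for trait in traits
    }
    shift = calibrate_frequency_shift(
        sumstats[shift_trait], shift_threshold, config.delta_target
    )
    matrix, labels = simulate_cohort_genotypes(
        sumstats[shift_trait], shift, config, seed=int(root.integers(2**31 - 1))
    )

    # Follow-up: score cases directly on the shifted trait's true frequencies
    # scale-free stand-in — use a score-level draw tied to the case shift.
    n_follow = min(19, config.n_cases)
    case_scores, _ = simulate_score_cohort(
        config.delta_target, n_follow, 1, seed=int(root.integers(2**31 - 1))
    )
    follow_scores = ScoreSet(
        sample_ids=[f"case{i + 1:03d}" for i in range(n_follow)],
        raw_score=case_scores.raw_score[:n_follow],
        trait_label=shift_trait,
        threshold=None,
        n_snps_included=None,
    )
    phenotypes = simulate_followup_phenotypes(
        follow_scores, seed=int(root.integers(2**31 - 1))
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for trait, ss in sumstats.items():
            write_summary_stats(ss, outdir / f"{trait}_sumstats.tsv")
        write_genotypes_vcf(matrix, outdir / "genotypes.vcf")
        write_phenotypes(phenotypes, outdir / "phenotypes.csv")
    return StudyData(
        sumstats=sumstats,
        matrix=matrix,
        labels=labels,
        phenotypes=phenotypes,
        shift=shift,
        config=config,
    )
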