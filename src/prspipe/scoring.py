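"""P-value-threshold variant selection, additive weighted scoring, and
standardization.

A score for sample *i* is the plain weighted sum of effect-allele dosages,
``raw_i = sum_j w_j * d_ij``, over the variants whose GWAS P-value falls
strictly below the threshold — no LD clumping (the scoring model assumes
independent variants) and no division by the number of variants.  Scores
are standardized to mean 0 / SD 1 over the combined cohort (cases and
reference together) so a case mean above 0 reads directly as risk-allele
enrichment in SD units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from prspipe.io import GenotypeMatrix, SummaryStatSet
from prspipe.qc import Harmonized, harmonize

#: The standard threshold grid for SNP inclusion.
DEFAULT_THRESHOLDS = (0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0)

MISSING_POLICIES = ("mean_impute", "zero", "exclude")


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ScoreSet:
    """Per-sample raw and standardized PRS for one (trait, threshold) cell."""

    sample_ids: list[str]
    raw_score: np.ndarray
    trait_label: str
    threshold: float | None
    n_snps_included: int | None
    std_score: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def values(self) -> np.ndarray:
        """Standardized scores when available, else raw."""
        return self.raw_score if self.std_score is None else self.std_score


@dataclass(frozen=True)
class ScoreGrid:
    """Score sets for every non-empty (trait, threshold) cell."""

    scores: list[ScoreSet]
    skipped: list[tuple[str, float, str]]  # (trait, threshold, reason)

    def __iter__(self):
        return iter(self.scores)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.scores:
            std = s.std_score if s.std_score is not None else [np.nan] * s.n_samples
            for sid, raw, z in zip(s.sample_ids, s.raw_score, std):
                rows.append(
                    {
                        "sample": sid,
                        "trait": s.trait_label,
                        "threshold": s.threshold,
                        "raw": raw,
                        "standardized": z,
                        "n_snps": s.n_snps_included,
                    }
                )
        return pd.DataFrame(rows)


def select_snps(sumstats: SummaryStatSet, p_threshold: float) -> SummaryStatSet:
    """Variants with GWAS P strictly below ``p_threshold``.

    The strict ``<`` convention means P = 1 rows never enter a score, even
    at the loosest threshold.  An empty selection is returned as an empty
    set (the grid runner records n_snps = 0 and skips the cell).
    """
    if not 0 < p_threshold <= 1:
        raise ScoringError(f"p_threshold must be in (0, 1], got {p_threshold}")
    return sumstats.subset(sumstats.table["p_value"] < p_threshold)


def compute_raw_prs(
    harmonized: Harmonized,
    selected_ids: Iterable[str] | None = None,
    missing_policy: str = "mean_impute",
) -> ScoreSet:
    """Additive weighted score over the (optionally selected) variants.

    Missing dosages are handled per ``missing_policy``: ``mean_impute``
    (default) substitutes the variant's mean non-missing dosage so score
    scale stays comparable across samples, ``zero`` substitutes 0, and
    ``exclude`` drops any variant with a missing value in any sample.
    Variants with all dosages missing are dropped with a warning.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ScoringError(f"unknown missing_policy {missing_policy!r}; use {MISSING_POLICIES}")
    table = harmonized.table
    dosage = harmonized.dosage
    if selected_ids is not None:
        wanted = set(selected_ids)
        mask = table["id"].isin(wanted).to_numpy()
        table = table.loc[mask]
        dosage = dosage[:, mask]

    w = table["weight"].to_numpy(dtype=float)
    D = dosage.copy()
    all_missing = np.isnan(D).all(axis=0)
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} variant(s) with all dosages missing dropped",
            stacklevel=2,
        )
        D, w = D[:, ~all_missing], w[~all_missing]
    if missing_policy == "mean_impute":
        col_mean = np.nanmean(D, axis=0) if D.size else np.array([])
        idx = np.where(np.isnan(D))
        D[idx] = col_mean[idx[1]]
    elif missing_policy == "zero":
        D = np.nan_to_num(D, nan=0.0)
    else:  # exclude
        complete = ~np.isnan(D).any(axis=0)
        D, w = D[:, complete], w[complete]

    raw = D @ w if D.size else np.zeros(len(harmonized.sample_ids))
    return ScoreSet(
        sample_ids=list(harmonized.sample_ids),
        raw_score=raw,
        trait_label=harmonized.trait_label,
        threshold=None,
        n_snps_included=D.shape[1] if D.size else 0,
    )


def standardize_scores(scores: ScoreSet, reference_mask: np.ndarray | None = None) -> ScoreSet:
    """Standardize to mean 0 / SD 1 (sample SD, ddof=1).

    By default the location and scale come from the combined cohort; pass
    ``reference_mask`` to centre and scale on the reference subset only.
    Constant raw scores have no scale and raise :class:`ScoringError`.
    """
    if scores.n_samples < 2:
        raise ScoringError("standardization needs at least 2 samples")
    basis = scores.raw_score if reference_mask is None else scores.raw_score[reference_mask]
    if basis.size < 2:
        raise ScoringError("reference subset too small to standardize on")
    mu = basis.mean()
    sd = basis.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ScoringError(
            f"constant raw scores for {scores.trait_label!r} "
            f"(threshold {scores.threshold}): zero variance"
        )
    return replace(scores, std_score=(scores.raw_score - mu) / sd)


def score_one(
    harmonized: Harmonized,
    p_threshold: float,
    missing_policy: str = "mean_impute",
    standardize: bool = True,
) -> ScoreSet:
    """Score one (trait, threshold) cell from harmonized inputs."""
    mask = (harmonized.table["p_value"] < p_threshold).to_numpy()
    if not mask.any():
        return ScoreSet(
            sample_ids=list(harmonized.sample_ids),
            raw_score=np.zeros(len(harmonized.sample_ids)),
            trait_label=harmonized.trait_label,
            threshold=p_threshold,
            n_snps_included=0,
        )
    scores = compute_raw_prs(
        harmonized,
        selected_ids=harmonized.table.loc[mask, "id"],
        missing_policy=missing_policy,
    )
    scores = replace(scores, threshold=p_threshold)
    if standardize:
        scores = standardize_scores(scores)
    return scores


def score_grid(
    matrix: GenotypeMatrix,
    sumstats_by_trait: Mapping[str, SummaryStatSet],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    missing_policy: str = "mean_impute",
    standardize: bool = True,
    drop_ambiguous: bool = True,
) -> ScoreGrid:
    """One ScoreSet per (trait, threshold), in deterministic order.

    Traits iterate in the mapping's order, thresholds ascending.  Cells
    whose threshold selects no variants are recorded in ``skipped`` with
    n_snps = 0 rather than raising.
    """
    if not sumstats_by_trait:
        raise ScoringError("need at least one trait")
    out: list[ScoreSet] = []
    skipped: list[tuple[str, float, str]] = []
    for trait, sumstats in sumstats_by_trait.items():
        hz = harmonize(sumstats, matrix, drop_ambiguous=drop_ambiguous)
        for pt in sorted(thresholds):
            cell = score_one(hz, pt, missing_policy=missing_policy, standardize=standardize)
            if cell.n_snps_included == 0:
                skipped.append((trait, pt, "no variants below threshold"))
            else:
                out.append(cell)
    return ScoreGrid(scores=out, skipped=skipped)
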