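"""Post-imputation variant filters, sample call-rate policy, and
summary-statistic / genotype allele harmonization.

The variant filter keeps variants with MAF strictly greater than 0.01 and
imputation INFO strictly greater than 0.9 (both configurable).  Samples
with a call rate below 95% are flagged but retained by default; removal is
an explicit opt-in.  Harmonization aligns each summary-statistic effect
allele with the genotype ALT allele, flipping dosages (2 - d) where the
effect allele is REF, and drops strand-ambiguous (A/T, C/G) variants by
default because they cannot be resolved without strand metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from prspipe.io import GenotypeMatrix, SummaryStatSet, _maf_from_dosage

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

CALL_RATE_FLAG_THRESHOLD = 0.95


class QCError(ValueError):
    """A QC step left nothing for downstream analysis."""


@dataclass(frozen=True)
class VariantFilterResult:
    matrix: GenotypeMatrix
    n_kept: int
    n_removed: int


@dataclass(frozen=True)
class SampleQCReport:
    """Per-sample call rates with the <95% flag.

    Flagged samples are never removed here; the flag is purely
    informational, matching the study policy of retaining every sample.
    """

    table: pd.DataFrame  # columns: sample, call_rate, flagged
    threshold: float = CALL_RATE_FLAG_THRESHOLD

    @property
    def n_flagged(self) -> int:
        return int(self.table["flagged"].sum())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass(frozen=True)
class Harmonized:
    """Summary statistics aligned with effect-allele dosage columns.

    ``dosage`` columns count copies of each variant's *effect* allele
    (flipped from ALT where needed), aligned with ``table`` rows; the
    stored weights are exactly the published ones — flips act on dosage,
    never on weight sign.
    """

    trait_label: str
    sample_ids: list[str]
    table: pd.DataFrame  # id, chrom, pos, effect_allele, other_allele, weight, p_value
    dosage: np.ndarray  # samples x aligned variants, effect-allele scale
    report: dict = field(default_factory=dict)

    @property
    def n_variants(self) -> int:
        return len(self.table)


def filter_variants(
    matrix: GenotypeMatrix, maf_min: float = 0.01, info_min: float = 0.9
) -> VariantFilterResult:
    """Keep variants with MAF > maf_min AND INFO > info_min (both strict).

    Raises :class:`QCError` if nothing survives, since scoring would be
    impossible.  Kept + removed always equals the input variant count and
    the filter is idempotent.
    """
    if matrix.n_variants == 0:
        raise QCError("empty genotype matrix")
    keep = (matrix.variants["maf"].to_numpy() > maf_min) & (
        matrix.variants["info_score"].to_numpy() > info_min
    )
    n_kept = int(keep.sum())
    if n_kept == 0:
        raise QCError(
            f"all {matrix.n_variants} variants removed by MAF>{maf_min} & INFO>{info_min}"
        )
    filtered = GenotypeMatrix(
        sample_ids=list(matrix.sample_ids),
        variants=matrix.variants.loc[keep].reset_index(drop=True),
        dosage=matrix.dosage[:, keep],
        warnings=dict(matrix.warnings),
    )
    return VariantFilterResult(matrix=filtered, n_kept=n_kept, n_removed=matrix.n_variants - n_kept)


def compute_sample_call_rates(
    matrix: GenotypeMatrix, flag_threshold: float = CALL_RATE_FLAG_THRESHOLD
) -> SampleQCReport:
    """Per-sample fraction of non-missing genotypes, flagged when < threshold."""
    if matrix.n_variants == 0:
        raise QCError("empty genotype matrix")
    call_rate = 1.0 - np.isnan(matrix.dosage).mean(axis=1)
    table = pd.DataFrame(
        {
            "sample": matrix.sample_ids,
            "call_rate": call_rate,
            "flagged": call_rate < flag_threshold,
        }
    )
    return SampleQCReport(table=table, threshold=flag_threshold)


def drop_flagged_samples(matrix: GenotypeMatrix, report: SampleQCReport) -> GenotypeMatrix:
    """Explicitly remove flagged samples (never done automatically)."""
    keep = ~report.table["flagged"].to_numpy()
    kept = matrix.dosage[keep, :]
    variants = matrix.variants.copy()
    variants["maf"] = _maf_from_dosage(kept)
    return GenotypeMatrix(
        sample_ids=[s for s, k in zip(matrix.sample_ids, keep) if k],
        variants=variants,
        dosage=kept,
        warnings=dict(matrix.warnings),
    )


def is_strand_ambiguous(effect: str, other: str) -> bool:
    return (effect, other) in AMBIGUOUS_PAIRS


def harmonize(
    sumstats: SummaryStatSet,
    matrix: GenotypeMatrix,
    drop_ambiguous: bool = True,
) -> Harmonized:
    """Align summary-statistic effect alleles with genotype dosages.

    Variants are joined on ID.  When the effect allele equals ALT the ALT
    dosage is used as-is; when it equals REF the dosage becomes ``2 - d``;
    allele pairs that match neither orientation are dropped and counted.
    Strand-ambiguous A/T and C/G variants are dropped by default.
    """
    ss = sumstats.table.set_index("id")
    geno = matrix.variants.set_index("id")
    common = ss.index.intersection(geno.index)
    report = {
        "sumstat_variants": len(ss),
        "genotype_variants": len(geno),
        "shared_ids": len(common),
        "matched": 0,
        "flipped": 0,
        "dropped_ambiguous": 0,
        "dropped_allele_mismatch": 0,
    }
    if len(common) == 0:
        raise QCError(
            f"no shared variant IDs between {sumstats.trait_label!r} "
            "summary statistics and genotypes"
        )

    col_of = {vid: j for j, vid in enumerate(matrix.variants["id"])}
    kept_rows, kept_cols = [], []
    for vid in common:
        s = ss.loc[vid]
        g = geno.loc[vid]
        ea, oa = s["effect_allele"], s["other_allele"]
        if drop_ambiguous and is_strand_ambiguous(ea, oa):
            report["dropped_ambiguous"] += 1
            continue
        j = col_of[vid]
        if ea == g["alt"] and oa == g["ref"]:
            col = matrix.dosage[:, j]
            report["matched"] += 1
        elif ea == g["ref"] and oa == g["alt"]:
            col = 2.0 - matrix.dosage[:, j]
            report["flipped"] += 1
        else:
            report["dropped_allele_mismatch"] += 1
            continue
        row = {
            "id": vid,
            "chrom": s["chrom"],
            "pos": s["pos"],
            "effect_allele": ea,
            "other_allele": oa,
            "weight": s["weight"],
            "p_value": s["p_value"],
        }
        kept_rows.append(row)
        kept_cols.append(col)

    if not kept_rows:
        raise QCError(f"zero variants matched after harmonization for {sumstats.trait_label!r}")
    table = pd.DataFrame(kept_rows)
    order = table.sort_values(["chrom", "pos"], kind="mergesort").index
    table = table.loc[order].reset_index(drop=True)
    dosage = np.column_stack([kept_cols[i] for i in order])
    return Harmonized(
        trait_label=sumstats.trait_label,
        sample_ids=list(matrix.sample_ids),
        table=table,
        dosage=dosage,
        report=report,
    )
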