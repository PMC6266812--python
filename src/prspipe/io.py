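"""Readers and writers for the file formats the pipeline touches.

Summary statistics are tab-delimited text with a header; genotypes are VCF
(plain or bgzipped) carrying either imputed dosages (``DS``) or hard
genotype calls (``GT``); phenotypes are CSV with binary symptom columns;
association results are written as TSV.  Readers validate strictly and drop
malformed optional rows with queryable warning counts rather than silently
coercing them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")

#: Default summary-statistic column names (the common SNP/CHR/BP/A1/A2/
#: BETA-or-OR/P/FRQ convention); override via ``column_map``.
DEFAULT_SUMSTAT_COLUMNS = {
    "id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "weight": "BETA",
    "p_value": "P",
    "effect_allele_freq": "FRQ",
}

#: Canonical follow-up symptoms and the allergic-disorder domain each
#: belongs to: asthma, allergic rhinitis, atopic dermatitis, food allergy.
SYMPTOM_DOMAINS = {
    "wheezing": "asthma",
    "dyspnoea": "asthma",
    "coughing_at_night": "asthma",
    "asthma_diagnosed": "asthma",
    "asthma_medication": "asthma",
    "irritated_nasal_mucosa": "allergic rhinitis",
    "irritated_eyes": "allergic rhinitis",
    "rhinitis_diagnosed": "allergic rhinitis",
    "rhinitis_medication": "allergic rhinitis",
    "eczema": "atopic dermatitis",
    "topical_steroids": "atopic dermatitis",
    "food_allergy": "food allergy",
}

_YES = {"1", "yes", "y", "true"}
_NO = {"0", "no", "n", "false"}
_MISSING = {"", "na", "nan", "none", "missing", "."}


class FormatError(ValueError):
    """A mandatory field is missing or malformed beyond repair."""


@dataclass(frozen=True)
class SummaryStatSet:
    """Per-variant GWAS results for one trait.

    ``table`` columns: id, chrom, pos, effect_allele, other_allele, weight
    (always on the log-odds / linear "beta" scale), p_value in (0, 1], and
    optional effect_allele_freq in (0, 1).
    """

    trait_label: str
    table: pd.DataFrame
    warnings: dict = field(default_factory=dict)

    @property
    def n_variants(self) -> int:
        return len(self.table)

    @property
    def odds_ratios(self) -> pd.Series:
        """OR view of the stored log-odds weights."""
        return np.exp(self.table["weight"])

    def subset(self, mask) -> "SummaryStatSet":
        return replace(self, table=self.table.loc[mask].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Samples x variants effect-allele (ALT) dosage matrix.

    ``dosage`` is float with NaN marking missing genotypes; every
    non-missing entry lies in [0, 2].  ``variants`` columns: id, chrom,
    pos, ref, alt, info_score in [0, 1], maf in [0, 0.5] (computed from
    non-missing dosages unless supplied).
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray
    warnings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.variants)):
            raise FormatError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        finite = self.dosage[~np.isnan(self.dosage)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise FormatError("non-missing dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)


@dataclass
class PhenotypeTable:
    """Per-subject binary symptom indicators with domain tags.

    ``data`` holds one column per symptom with values 0.0/1.0/NaN;
    ``domains`` maps every symptom column to one of the four allergic
    disorder domains.  Optional covariates (sex, age, IgE positivity) ride
    along in ``covariates``.
    """

    subject_ids: list[str]
    data: pd.DataFrame
    domains: dict[str, str]
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        untagged = [c for c in self.data.columns if c not in self.domains]
        if untagged:
            raise FormatError(f"symptom columns without a domain tag: {untagged}")
        vals = self.data.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0) | (vals == 1)
        if not ok.all():
            raise FormatError("symptom values must be 0, 1 or missing")

    @property
    def symptoms(self) -> list[str]:
        return list(self.data.columns)


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    effect_scale: str = "beta",
    trait_label: str | None = None,
) -> SummaryStatSet:
    """Read a tab-delimited GWAS summary-statistics file.

    ``effect_scale`` is ``"beta"`` (log-odds or linear weights, kept as is)
    or ``"or"`` (odds ratios, log-transformed once at ingest).  Rows with a
    P-value outside (0, 1], missing/invalid alleles, or a duplicate variant
    ID (first kept) are dropped, with counts recorded in ``.warnings``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"summary-statistics file not found: {path}")
    if effect_scale not in ("beta", "or"):
        raise FormatError(f"effect_scale must be 'beta' or 'or', got {effect_scale!r}")
    cols = dict(DEFAULT_SUMSTAT_COLUMNS)
    if column_map:
        cols.update(column_map)
    raw = pd.read_csv(path, sep="\t", dtype={cols["chrom"]: str})
    mandatory = ["id", "chrom", "pos", "effect_allele", "other_allele", "weight", "p_value"]
    for key in mandatory:
        if cols[key] not in raw.columns:
            raise FormatError(f"missing mandatory column {cols[key]!r} (maps to {key!r})")

    out = pd.DataFrame(
        {
            "id": raw[cols["id"]].astype(str),
            "chrom": raw[cols["chrom"]].astype(str),
            "pos": pd.to_numeric(raw[cols["pos"]], errors="coerce"),
            "effect_allele": raw[cols["effect_allele"]].astype(str).str.upper(),
            "other_allele": raw[cols["other_allele"]].astype(str).str.upper(),
            "weight": pd.to_numeric(raw[cols["weight"]], errors="coerce"),
            "p_value": pd.to_numeric(raw[cols["p_value"]], errors="coerce"),
        }
    )
    if cols["effect_allele_freq"] in raw.columns:
        out["effect_allele_freq"] = pd.to_numeric(raw[cols["effect_allele_freq"]], errors="coerce")

    warns: dict[str, int] = {}
    bad_p = ~(out["p_value"] > 0) | ~(out["p_value"] <= 1)
    bad_allele = (
        ~out["effect_allele"].isin(VALID_ALLELES)
        | ~out["other_allele"].isin(VALID_ALLELES)
        | (out["effect_allele"] == out["other_allele"])
    )
    bad_weight = out["weight"].isna()
    if effect_scale == "or":
        bad_weight |= ~(out["weight"] > 0)
    drop = bad_p | bad_allele | bad_weight | out["pos"].isna()
    warns["dropped_bad_p"] = int(bad_p.sum())
    warns["dropped_bad_allele"] = int(bad_allele.sum())
    warns["dropped_bad_weight"] = int((bad_weight & ~bad_p & ~bad_allele).sum())
    out = out.loc[~drop]

    dup = out["id"].duplicated(keep="first")
    warns["dropped_duplicate_id"] = int(dup.sum())
    out = out.loc[~dup]
    if out.empty:
        raise FormatError(f"no valid variants survived validation in {path}")

    if effect_scale == "or":
        out["weight"] = np.log(out["weight"])
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if any(warns.values()):
        warnings.warn(f"{path.name}: dropped rows {warns}", stacklevel=2)
    return SummaryStatSet(trait_label=trait_label or path.stem, table=out, warnings=warns)


def write_summary_stats(sumstats: SummaryStatSet, path: str | Path) -> None:
    """Write a SummaryStatSet back to the default tab-delimited layout."""
    t = sumstats.table
    out = pd.DataFrame(
        {
            "SNP": t["id"],
            "CHR": t["chrom"],
            "BP": t["pos"],
            "A1": t["effect_allele"],
            "A2": t["other_allele"],
            "BETA": t["weight"],
            "P": t["p_value"],
        }
    )
    if "effect_allele_freq" in t.columns:
        out["FRQ"] = t["effect_allele_freq"]
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_genotypes_vcf(
    path: str | Path,
    dosage_field: str = "DS",
    info_key: str = "INFO",
) -> GenotypeMatrix:
    """Read biallelic variants from a VCF into an ALT-dosage matrix.

    With ``dosage_field="DS"`` fractional imputed dosages are preserved;
    with ``"GT"`` hard calls are converted to 0/1/2 ALT counts and ``./.``
    becomes missing.  The per-variant imputation quality is taken from the
    INFO key named ``info_key`` when present, else 1.0.  Multiallelic
    records are skipped with a warning count; an empty VCF is a hard error.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FormatError(f"VCF not found: {path}")
    if dosage_field not in ("DS", "GT"):
        raise FormatError(f"dosage_field must be 'DS' or 'GT', got {dosage_field!r}")

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, columns = [], []
    warns = {"skipped_multiallelic": 0, "skipped_no_dosage": 0}
    for rec in vcf:
        if len(rec.ALT) != 1:
            warns["skipped_multiallelic"] += 1
            continue
        if dosage_field == "DS":
            ds = rec.format("DS")
            if ds is None:
                warns["skipped_no_dosage"] += 1
                continue
            col = np.asarray(ds, dtype=float).reshape(-1)
            col[col < 0] = np.nan  # cyvcf2 encodes missing floats as negative sentinels
        else:
            gts = np.asarray(rec.genotypes)  # (n_samples, 3): allele, allele, phased
            alleles = gts[:, :2].astype(float)  # -1 = missing allele
            alleles[alleles < 0] = np.nan
            col = alleles.sum(axis=1)
        info = rec.INFO.get(info_key)
        rows.append(
            {
                "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "info_score": float(info) if info is not None else 1.0,
            }
        )
        columns.append(col)
    vcf.close()
    if not rows:
        raise FormatError(f"no usable biallelic records in {path}")

    dosage = np.column_stack(columns)
    variants = pd.DataFrame(rows)
    variants["maf"] = _maf_from_dosage(dosage)
    if any(warns.values()):
        warnings.warn(f"{path.name}: {warns}", stacklevel=2)
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants, dosage=dosage, warnings=warns)


def _maf_from_dosage(dosage: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per variant from non-missing ALT dosages."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        freq = np.nanmean(dosage, axis=0) / 2.0
    return np.minimum(freq, 1.0 - freq)


def write_genotypes_vcf(matrix: GenotypeMatrix, path: str | Path, info_key: str = "INFO") -> None:
    """Write a GenotypeMatrix as a VCF with DS (dosage) and GT fields."""
    import pysam

    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(matrix.variants["chrom"].astype(str)):
        header.contigs.add(chrom)
    header.info.add(info_key, 1, "Float", "Imputation quality score")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DS", 1, "Float", "ALT allele dosage")
    for s in matrix.sample_ids:
        header.add_sample(s)

    order = matrix.variants.sort_values(["chrom", "pos"], kind="mergesort").index
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in order:
            v = matrix.variants.loc[j]
            rec = out.new_record(
                contig=str(v["chrom"]),
                start=int(v["pos"]) - 1,
                stop=int(v["pos"]),
                alleles=(str(v["ref"]), str(v["alt"])),
                id=str(v["id"]),
            )
            rec.info[info_key] = float(v["info_score"])
            for i, s in enumerate(matrix.sample_ids):
                d = matrix.dosage[i, j]
                if math.isnan(d):
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["DS"] = float(d)
                    k = int(round(d))
                    rec.samples[s]["GT"] = ((0, 0), (0, 1), (1, 1))[min(max(k, 0), 2)]
            out.write(rec)


def read_phenotypes(
    path: str | Path,
    domain_map: Mapping[str, str] | None = None,
    subject_col: str = "subject_id",
) -> PhenotypeTable:
    """Read a binary symptom CSV into canonical 0/1/missing coding.

    Symptom values may be 1/0, yes/no, y/n or true/false (case-insensitive);
    anything else is a hard error listing the offending values.  Columns are
    assigned to the four allergic-disorder domains via the built-in registry
    (``SYMPTOM_DOMAINS``) extended by ``domain_map``; ``sex``, ``age`` and
    ``ige_positive`` are treated as covariates.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"phenotype file not found: {path}")
    raw = pd.read_csv(path, dtype=str)
    if subject_col not in raw.columns:
        raise FormatError(f"missing subject ID column {subject_col!r}")
    domains = dict(SYMPTOM_DOMAINS)
    if domain_map:
        domains.update(domain_map)

    covariate_cols = [c for c in ("sex", "age", "ige_positive") if c in raw.columns]
    symptom_cols = [c for c in raw.columns if c != subject_col and c not in covariate_cols]
    unknown = [c for c in symptom_cols if c not in domains]
    if unknown:
        raise FormatError(f"symptom columns without a known domain: {unknown}")

    data = {}
    for col in symptom_cols:
        vals = raw[col].astype(str).str.strip().str.lower()
        bad = sorted(set(vals) - _YES - _NO - _MISSING)
        if bad:
            raise FormatError(f"unrecognized encoding in column {col!r}: {bad}")
        data[col] = vals.map(lambda v: 1.0 if v in _YES else (0.0 if v in _NO else np.nan))
    covariates = raw[covariate_cols].copy() if covariate_cols else None
    return PhenotypeTable(
        subject_ids=list(raw[subject_col]),
        data=pd.DataFrame(data),
        domains={c: domains[c] for c in symptom_cols},
        covariates=covariates,
    )


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    out = pd.DataFrame({"subject_id": table.subject_ids})
    if table.covariates is not None:
        out = pd.concat([out, table.covariates.reset_index(drop=True)], axis=1)
    for col in table.data.columns:
        out[col] = table.data[col].map({1.0: "yes", 0.0: "no"}).fillna("")
    out.to_csv(path, index=False)


ASSOCIATION_COLUMNS = [
    "trait", "threshold", "n_snps", "delta", "t_stat", "t_p",
    "OR", "ci_low", "ci_high", "P", "n_case", "n_control", "status",
]


def write_association_table(results: Sequence, path: str | Path) -> None:
    """Write association results as TSV (trait x threshold grid rows)."""
    rows = []
    for r in results:
        rows.append(
            {
                "trait": r.trait_label,
                "threshold": r.threshold,
                "n_snps": r.n_snps,
                "delta": r.delta,
                "t_stat": r.t_stat,
                "t_p": r.t_p,
                "OR": r.or_per_sd,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "P": r.wald_p,
                "n_case": r.n_case,
                "n_control": r.n_control,
                "status": r.status,
            }
        )
    pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_association_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
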