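"""End-to-end orchestration: read -> QC -> harmonize -> score grid ->
associations -> exports, with a validated, fully serialized configuration.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator

from prspipe import association as assoc
from prspipe import io, qc, scoring

log = logging.getLogger("prspipe")


class PipelineError(RuntimeError):
    """A stage hit a hard error; the message names the stage."""


class PipelineConfig(BaseModel):
    """Validated run configuration; the resolved copy is written with outputs."""

    sumstats: dict[str, str]  # trait label -> summary-stats TSV path
    genotypes: str
    phenotypes: str | None = None
    out_dir: str = "prspipe_run"
    effect_scale: Literal["beta", "or"] = "beta"
    dosage_field: Literal["DS", "GT"] = "DS"
    info_key: str = "INFO"
    thresholds: list[float] = Field(default=list(scoring.DEFAULT_THRESHOLDS))
    maf_min: float = 0.01
    info_min: float = 0.9
    call_rate_flag: float = 0.95
    drop_flagged_samples: bool = False
    drop_ambiguous: bool = True
    missing_policy: Literal["mean_impute", "zero", "exclude"] = "mean_impute"
    standardization: Literal["combined", "reference"] = "combined"
    welch: bool = False
    bonferroni: bool = False
    #: (trait, threshold) score cells tested against follow-up symptoms.
    symptom_cells: list[tuple[str, float]] = Field(
        default=[("asthma", 0.001), ("asthma", 1.0), ("asd", 0.001), ("asd", 0.01)]
    )
    case_prefix: str = "case"
    seed: int = 42

    @field_validator("thresholds")
    @classmethod
    def _check_thresholds(cls, v: list[float]) -> list[float]:
        if not v or any(not 0 < t <= 1 for t in v):
            raise ValueError("thresholds must be non-empty and each in (0, 1]")
        return sorted(v)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _setup_logging(run_dir: Path, verbose: bool) -> None:
    log.setLevel(logging.DEBUG)
    log.handlers.clear()
    fh = logging.FileHandler(run_dir / "pipeline.log", mode="w")
    fh.setLevel(logging.DEBUG)
    ch = logging.StreamHandler()
    ch.setLevel(logging.DEBUG if verbose else logging.INFO)
    fmt = logging.Formatter("%(levelname)s %(message)s")
    for h in (fh, ch):
        h.setFormatter(fmt)
        log.addHandler(h)


def run_full_pipeline(config: PipelineConfig, verbose: bool = False) -> Path:
    """Execute the whole analysis and return the run directory.

    Outputs: ``association_grid.tsv`` (trait x threshold ORs per SD),
    ``scores.tsv``, ``sample_qc.tsv``, ``phenotype_summary.tsv`` and
    ``symptom_associations.tsv`` when phenotypes are given, plus
    ``pipeline.log`` and the resolved ``config.yaml``.
    """
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(run_dir, verbose)
    config.to_yaml(run_dir / "config.yaml")

    read_geno = _stage("read_genotypes")(io.read_genotypes_vcf)
    matrix = read_geno(config.genotypes, dosage_field=config.dosage_field, info_key=config.info_key)
    log.info("read %d samples x %d variants", matrix.n_samples, matrix.n_variants)
    if matrix.warnings:
        log.warning("genotype reader warnings: %s", matrix.warnings)

    sumstats = {}
    for trait, path in config.sumstats.items():
        ss = _stage("read_summary_stats")(io.read_summary_stats)(
            path, effect_scale=config.effect_scale, trait_label=trait
        )
        log.info("trait %s: %d variants (warnings %s)", trait, ss.n_variants, ss.warnings)
        sumstats[trait] = ss

    report = _stage("sample_qc")(qc.compute_sample_call_rates)(matrix, config.call_rate_flag)
    report.to_tsv(run_dir / "sample_qc.tsv")
    log.info(
        "sample QC: %d of %d flagged below %.0f%% call rate (retained)",
        report.n_flagged, matrix.n_samples, 100 * config.call_rate_flag,
    )
    if config.drop_flagged_samples and report.n_flagged:
        matrix = qc.drop_flagged_samples(matrix, report)
        log.info("dropped %d flagged samples on request", report.n_flagged)

    filt = _stage("variant_qc")(qc.filter_variants)(matrix, config.maf_min, config.info_min)
    matrix = filt.matrix
    log.info(
        "variant QC (MAF>%g & INFO>%g): kept %d, removed %d",
        config.maf_min, config.info_min, filt.n_kept, filt.n_removed,
    )

    is_case = [s.startswith(config.case_prefix) for s in matrix.sample_ids]
    import numpy as np

    labels = np.asarray(is_case, dtype=bool)
    if not labels.any() or labels.all():
        raise PipelineError(
            f"stage 'labels' failed: sample IDs must contain both "
            f"{config.case_prefix!r}-prefixed cases and others"
        )
    log.info("cohort: %d cases, %d reference", int(labels.sum()), int((~labels).sum()))

    grid = _stage("scoring")(scoring.score_grid)(
        matrix,
        sumstats,
        thresholds=config.thresholds,
        missing_policy=config.missing_policy,
        standardize=config.standardization == "combined",
        drop_ambiguous=config.drop_ambiguous,
    )
    if config.standardization == "reference":
        grid = scoring.ScoreGrid(
            scores=[scoring.standardize_scores(s, ~labels) for s in grid.scores],
            skipped=grid.skipped,
        )
    for s in grid:
        log.debug("cell %s @ %g: n_snps=%d", s.trait_label, s.threshold, s.n_snps_included)
    for trait, pt, reason in grid.skipped:
        log.warning("skipped cell %s @ %g: %s", trait, pt, reason)
    grid.to_frame().to_csv(run_dir / "scores.tsv", sep="\t", index=False, float_format="%.17g")

    results = _stage("association")(assoc.association_grid)(
        grid, labels, equal_var=not config.welch
    )
    io.write_association_table(results, run_dir / "association_grid.tsv")
    log.info("association grid: %d cells written", len(results))

    if config.phenotypes:
        phenos = _stage("read_phenotypes")(io.read_phenotypes)(config.phenotypes)
        assoc.summarize_phenotypes(phenos).to_csv(
            run_dir / "phenotype_summary.tsv", sep="\t", index=False, float_format="%.17g"
        )
        rows = []
        by_cell = {(s.trait_label, s.threshold): s for s in grid}
        follow_ids = set(phenos.subject_ids)
        for trait, pt in config.symptom_cells:
            cell = by_cell.get((trait, pt))
            if cell is None:
                log.warning("symptom layer: no score cell for %s @ %g", trait, pt)
                continue
            keep = [i for i, sid in enumerate(cell.sample_ids) if sid in follow_ids]
            sub = scoring.ScoreSet(
                sample_ids=[cell.sample_ids[i] for i in keep],
                raw_score=cell.raw_score[keep],
                std_score=None if cell.std_score is None else cell.std_score[keep],
                trait_label=cell.trait_label,
                threshold=cell.threshold,
                n_snps_included=cell.n_snps_included,
            )
            for r in _stage("symptom_association")(assoc.symptom_association)(
                sub, phenos, bonferroni=config.bonferroni
            ):
                rows.append({"trait": trait, "threshold": pt, **r.__dict__})
        if rows:
            import pandas as pd

            pd.DataFrame(rows).to_csv(
                run_dir / "symptom_associations.tsv", sep="\t", index=False, float_format="%.17g"
            )
            log.info("symptom associations: %d rows written", len(rows))

    log.info("run complete: %s", run_dir)
    return run_dir
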