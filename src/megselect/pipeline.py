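"""End-to-end orchestration of one analysis category and cross-category reports.

A *category* is one subtype x one ordering (pathologic stage, risk-of-death
quartile, or age quartile): filter the cohort, build the ordered labeling,
scan both directions for monotone genes, and write a results table plus a
JSON summary. ``run_all`` then compares categories: overlap of their
significant gene sets, Spearman association between the stage and risk
labelings, and a Kaplan-Meier / log-rank comparison of the stages.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, io_clinical, mfselector, stratification
from .containers import ClinicalTable, ExpressionMatrix, OrderedLabeling
from .exceptions import DomainError, PipelineError
from .mfselector import DIRECTIONS, MEGResults

logger = logging.getLogger(__name__)

LABELING_KINDS = ("stage", "risk", "age")


@dataclass
class RunConfig:
    """Configuration of one category run."""

    expression_path: str | Path
    clinical_path: str | Path
    labeling: str  # stage | risk | age
    name: str = ""  # e.g. "AC_risk"; defaults to subtype_labeling
    subtype: str | None = None
    directions: tuple[str, ...] = DIRECTIONS
    B: int = 1000
    seed: int = 0
    alpha: float = 0.05
    require_uncensored: bool = True
    stages: tuple[str, ...] | None = None
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.labeling not in LABELING_KINDS:
            raise DomainError(f"labeling must be one of {LABELING_KINDS}")
        bad = set(self.directions) - set(DIRECTIONS)
        if bad or not self.directions:
            raise DomainError(f"directions must be drawn from {DIRECTIONS}")
        if not 0 < self.alpha < 1:
            raise DomainError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.B < 1:
            raise DomainError(f"permutation count B must be >= 1, got {self.B}")
        if not self.name:
            self.name = f"{self.subtype or 'all'}_{self.labeling}"


@dataclass
class CategoryResult:
    """Outputs of one category: per-direction scan results and the summary."""

    name: str
    results: dict[str, MEGResults]
    labeling: OrderedLabeling
    clinical: ClinicalTable
    summary: dict = field(default_factory=dict)

    @property
    def significant_genes(self) -> set[str]:
        out: set[str] = set()
        for res in self.results.values():
            out |= set(res.significant_genes)
        return out


def _derive_seed(seed: int, *path: int) -> int:
    """A reproducible child seed, kept below 2**31."""
    return int(np.random.SeedSequence([seed, *path]).generate_state(1)[0] % (2**31))


def _build_labeling(clin: ClinicalTable, kind: str) -> OrderedLabeling:
    if kind == "stage":
        return stratification.assign_stage_groups(clin)
    if kind == "risk":
        return stratification.assign_risk_groups(clin)
    return stratification.assign_age_groups(clin)


def run_category(config: RunConfig) -> CategoryResult:
    """Run filter -> stratify -> scan -> write for one category."""
    t0 = time.perf_counter()

    def _stage(stage_name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage '{stage_name}' failed: {exc}") from exc

    expr = _stage("read expression", io_clinical.read_expression_matrix,
                  config.expression_path)
    clin = _stage("read clinical", io_clinical.read_clinical_table,
                  config.clinical_path)
    clin = _stage(
        "filter patients",
        stratification.filter_patients,
        clin,
        require_uncensored=config.require_uncensored,
        subtypes={config.subtype} if config.subtype else None,
        stages=set(config.stages) if config.stages else None,
    )
    expr, clin = _stage("align samples", io_clinical.align_samples, expr, clin)
    labeling = _stage(f"stratify ({config.labeling})", _build_labeling,
                      clin, config.labeling)

    results: dict[str, MEGResults] = {}
    direction_seeds: dict[str, int] = {}
    for i, direction in enumerate(config.directions):
        child = _derive_seed(config.seed, i)
        direction_seeds[direction] = child
        results[direction] = _stage(
            f"scan ({direction})",
            mfselector.select_megs,
            expr, labeling, direction=direction,
            B=config.B, seed=child, alpha=config.alpha,
        )

    summary = {
        "category": config.name,
        "labeling": config.labeling,
        "subtype": config.subtype,
        "n_samples": len(clin),
        "n_genes": expr.shape[0],
        "K": labeling.K,
        "n_k": list(labeling.n_k),
        "level_names": list(labeling.level_names),
        "B": config.B,
        "seed": config.seed,
        "direction_seeds": direction_seeds,
        "alpha": config.alpha,
        # wall-clock timing is logged, not written: outputs stay byte-identical
        "n_significant": {
            direction: {
                "0.05": res.n_significant(0.05),
                "0.1": res.n_significant(0.1),
                f"{config.alpha}": res.n_significant(config.alpha),
            }
            for direction, res in results.items()
        },
    }
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for direction, res in results.items():
            io_clinical.write_results_table(
                res, outdir / f"{config.name}_{direction}.tsv"
            )
        (outdir / f"{config.name}_summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n"
        )
    logger.info("category %s done in %.2fs", config.name, time.perf_counter() - t0)
    return CategoryResult(name=config.name, results=results, labeling=labeling,
                          clinical=clin, summary=summary)


def run_all(
    categories: list[CategoryResult],
    top_n_fallback: int | None = None,
) -> dict:
    """Cross-category report: gene-set overlap plus stage-vs-risk association.

    The overlap uses each category's significant set; if a category has no
    significant genes and ``top_n_fallback`` is given, its ``top_n_fallback``
    smallest-q genes stand in. Stage-vs-risk association (Spearman and a
    stage-stratified log-rank test) is computed per category whose clinical
    table carries stages for its samples.
    """
    if len(categories) < 2:
        raise DomainError("cross-category report needs at least 2 completed categories")

    gene_sets: dict[str, set] = {}
    for cat in categories:
        genes = cat.significant_genes
        if not genes and top_n_fallback:
            ranked: list[str] = []
            for res in cat.results.values():
                top = res.table.sort_values(["q_value", "de_total", "gene"]).head(
                    top_n_fallback
                )
                ranked.extend(top["gene"])
            genes = set(ranked)
        gene_sets[cat.name] = genes
    overlap = association.overlap_summary(gene_sets)

    universes = {cat.name: tuple(cat.clinical.sample_ids) for cat in categories}
    shared = set.intersection(*(set(u) for u in universes.values()))
    mismatched = {n: len(set(u) - shared) for n, u in universes.items()
                  if set(u) != shared}
    if mismatched:
        logger.warning("run_all: categories cover different sample universes: %s",
                       mismatched)

    per_category: dict[str, dict] = {}
    for cat in categories:
        clin = cat.clinical.data
        entry: dict = {}
        if clin["stage"].notna().all() and clin["stage"].nunique() >= 2:
            stage_lab = stratification.assign_stage_groups(cat.clinical)
            try:
                risk_lab = stratification.assign_risk_groups(cat.clinical)
                ids = cat.clinical.sample_ids
                rho, p = association.spearman_ordinal(
                    stage_lab.levels_for(ids), risk_lab.levels_for(ids)
                )
                entry["spearman_stage_vs_risk"] = {"rho": rho, "p_value": p}
            except DomainError as exc:
                entry["spearman_stage_vs_risk"] = {"error": str(exc)}
            comp = association.logrank_km(
                clin["os_time"], clin["event"], clin["stage"]
            )
            entry["logrank_by_stage"] = comp.to_json_dict()
        per_category[cat.name] = entry

    return {
        "categories": [cat.name for cat in categories],
        "significant_set_sizes": {n: len(s) for n, s in gene_sets.items()},
        "overlap": overlap.to_json_dict(),
        "mismatched_sample_universes": mismatched,
        "association": per_category,
    }
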