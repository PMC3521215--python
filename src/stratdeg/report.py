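"""Presentation utilities and the end-to-end pipeline driver.

Covers the tissue presence matrix (a gene is "observed" in a tissue when at
least one EST of either condition comes from it), the delta-Ct relative
expression helper for qPCR follow-up, and ``run_pipeline`` which chains
curate -> assign -> count -> test -> filter -> report with a manifest and a
run log recording every threshold used.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import candidate_filter, count_engine, est_assignment, library_curation
from . import stratified_stats, synthetic_data
from .config import PipelineConfig, configure_logging
from .count_engine import CountMatrix
from .errors import ConfigError, StageError, StratdegError, ValidationError

logger = logging.getLogger("stratdeg")


def presence_matrix(
    matrix: CountMatrix,
    genes: Sequence[str] | None = None,
    results: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Boolean genes x tissues grid: present iff >= 1 EST in either condition.

    When a results table is supplied, rows are ordered by descending MH
    common odds ratio (display convention); otherwise input order is kept.
    """
    genes = list(matrix.genes) if genes is None else list(genes)
    for g in genes:
        matrix.gene_index(g)  # raises on unknown gene
    idx = [matrix.gene_index(g) for g in genes]
    present = matrix.counts[idx].sum(axis=2) >= 1
    frame = pd.DataFrame(present, index=pd.Index(genes, name="gene"),
                         columns=matrix.tissues)
    if results is not None and "or_mh" in results.columns:
        order = (
            results.set_index("gene")["or_mh"]
            .reindex(genes)
            .sort_values(ascending=False, kind="mergesort")
            .index
        )
        frame = frame.loc[order]
    return frame


def qpcr_relative_expression(ct_gene: float, ct_reference: float) -> float:
    """Relative expression by the delta-Ct method: 2^-(Ct_gene - Ct_ref)."""
    if not (math.isfinite(ct_gene) and math.isfinite(ct_reference)):
        raise ValidationError("Ct values must be finite")
    return float(2.0 ** (-(ct_gene - ct_reference)))


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------


def _preflight(config: PipelineConfig) -> None:
    if config.simulate:
        return
    needed = []
    if config.counts:
        needed = [("counts", config.counts)]
    else:
        needed = [("libraries", config.libraries), ("psl", config.psl),
                  ("gene_map", config.gene_map), ("est_library", config.est_library)]
    for name, path in needed:
        if not path:
            raise ConfigError(f"config missing required input: {name}")
        if not Path(path).is_file():
            raise ConfigError(f"{name} file not found: {path}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full screen and write per-stage outputs.

    Returns a manifest dict (also written to ``manifest.json``) with output
    paths and summary tallies. Any stage failure raises
    :class:`StageError` naming the stage.
    """
    _preflight(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    configure_logging("INFO", outdir / "run.log")
    logger.info("thresholds: %s", {
        "min_library_ests": config.min_library_ests,
        "min_identity": config.min_identity,
        "min_aligned_length": config.min_aligned_length,
        "min_tissue_total": config.min_tissue_total,
        "alpha": config.alpha, "ci_level": config.ci_level,
        "ci_lower_min": config.ci_lower_min,
        "de_p_max": config.de_p_max, "logfc_min": config.logfc_min,
        "seed": config.seed,
    })
    manifest: dict = {"outputs": {}, "summary": {}, "seed": config.seed}

    # -- inputs (simulated or from files) ----------------------------------
    if config.simulate:
        corpus = synthetic_data.generate_library_corpus(
            n_libraries=config.sim_n_libraries,
            contamination=config.sim_contamination,
            seed=config.seed,
        )
        paths = synthetic_data.write_corpus(corpus, outdir / "simulated")
        manifest["outputs"]["simulated"] = {k: str(v) for k, v in paths.items()}
        records, issues = corpus.records, []
        psl = corpus.psl
        gene_map = corpus.transcript_to_gene
        est_library = corpus.est_library
    elif config.counts:
        records = None
    else:
        records, issues = library_curation.parse_library_records(
            config.libraries, dialect="tsv"
        )
        for issue in issues:
            logger.warning("library parse: %s: %s", issue.location, issue.message)
        psl = est_assignment.read_psl(config.psl)
        gene_map = est_assignment.read_gene_map(config.gene_map)
        est_library = pd.read_csv(config.est_library, sep="\t", dtype=str)

    if config.counts and not config.simulate:
        matrix = _stage("count", CountMatrix.from_tsv, config.counts)
    else:
        overrides = (library_curation.read_overrides_tsv(config.overrides)
                     if config.overrides else None)
        decisions = _stage(
            "curate", library_curation.curate_libraries, records,
            exclusion_keywords=config.exclusion_keywords,
            min_est_count=config.min_library_ests,
            overrides=overrides,
        )
        library_curation.write_curation_tsv(decisions, outdir / "curation.tsv")
        manifest["outputs"]["curation"] = str(outdir / "curation.tsv")
        tally = library_curation.discard_tally(decisions)
        manifest["summary"]["libraries_total"] = len(decisions)
        manifest["summary"]["libraries_retained"] = sum(d.retained for d in decisions)
        manifest["summary"]["discard_tally"] = dict(tally)

        hits = _stage("assign", est_assignment.hits_from_psl, psl)
        assignments, unassigned = _stage(
            "assign", est_assignment.assign_best_hits, hits,
            min_identity=config.min_identity,
            min_length=config.min_aligned_length,
        )
        assignments = est_assignment.attach_libraries(assignments, est_library)
        assignments.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
        (outdir / "unassigned.txt").write_text("\n".join(unassigned) + "\n")
        manifest["outputs"]["assignments"] = str(outdir / "assignments.tsv")
        manifest["summary"]["ests_assigned"] = len(assignments)
        manifest["summary"]["ests_unassigned"] = len(unassigned)

        retained_libs = {d.library_id for d in decisions if d.retained}
        kept = assignments[assignments["library_id"].isin(retained_libs)]
        per_library = _stage("count", est_assignment.collapse_to_genes, kept, gene_map)
        matrix = _stage("count", count_engine.tabulate_counts, per_library, decisions)

    matrix = _stage("count", count_engine.apply_tissue_cutoff, matrix,
                    config.min_tissue_total)
    matrix.to_tsv(outdir / "counts.tsv")
    manifest["outputs"]["counts"] = str(outdir / "counts.tsv")
    manifest["summary"]["grand_total"] = matrix.grand_total
    manifest["summary"]["retained_tissues"] = matrix.retained_tissues

    results = _stage(
        "test", stratified_stats.run_all_genes, matrix,
        alpha=config.alpha, ci_lower_min=config.ci_lower_min,
        ci_level=config.ci_level,
        continuity_correction=config.continuity_correction,
        ci_method=config.ci_method,
    )
    stratified_stats.write_results_tsv(results, outdir / "results.tsv")
    manifest["outputs"]["results"] = str(outdir / "results.tsv")
    manifest["summary"]["genes_tested"] = len(results)
    manifest["summary"]["genes_selected"] = int(results["selected"].sum())
    manifest["summary"]["simpson_reversed"] = int(
        (results["simpson_flag"] == "reversed").sum()
    )

    if config.de_tables:
        de = pd.concat(
            [candidate_filter.read_de_table(p) for p in config.de_tables],
            ignore_index=True,
        )
        catalog = None
        if config.secretory or config.membrane:
            catalog = candidate_filter.AnnotationCatalog.from_sources(
                [(Path(p).stem, candidate_filter.read_gene_list(p))
                 for p in config.secretory],
                [(Path(p).stem, candidate_filter.read_gene_list(p))
                 for p in config.membrane],
            )
        candidates = _stage(
            "filter", candidate_filter.build_candidates, results, de, catalog,
            p_max=config.de_p_max, logfc_min=config.logfc_min,
        )
        candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        manifest["outputs"]["candidates"] = str(outdir / "candidates.tsv")
        manifest["summary"]["candidates"] = len(candidates)
        if catalog is not None and "localization" in candidates.columns:
            manifest["summary"]["localization"] = candidate_filter.localization_counts(
                dict(zip(candidates["gene"], candidates["localization"]))
            )

    presence = presence_matrix(matrix, results=results)
    presence.astype(int).to_csv(outdir / "presence_matrix.tsv", sep="\t")
    manifest["outputs"]["presence_matrix"] = str(outdir / "presence_matrix.tsv")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _stage(name: str, func, *args, **kwargs):
    try:
        return func(*args, **kwargs)
    except StageError:
        raise
    except StratdegError as exc:
        raise StageError(name, str(exc)) from exc
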