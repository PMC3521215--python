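"""Candidate triage: microarray cross-reference and localization annotation.

The stratified EST screen produces a primary candidate list; it is narrowed
by (1) intersecting with per-experiment microarray DE gene sets (p < 0.05,
log2 fold change > 1.0, strict) and taking the union of the intersections,
and (2) tagging candidates as secretory and/or membrane proteins from
merged annotation catalogs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import DEFAULT_DE_P_MAX, DEFAULT_LOGFC_MIN
from .errors import ValidationError

logger = logging.getLogger("stratdeg")

LOCALIZATIONS = ("secretory_only", "membrane_only", "both", "neither")


@dataclass(frozen=True)
class DERecord:
    """One gene's microarray DE result in one experiment."""

    gene_id: str
    p_value: float
    log_fc: float
    experiment_id: str

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"{self.gene_id}: p-value out of [0,1]")


@dataclass
class AnnotationCatalog:
    """Deduplicated secretory/membrane gene sets with per-source provenance."""

    secretory: dict[str, list[str]] = field(default_factory=dict)
    membrane: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_sources(
        cls,
        secretory_sources: Sequence[tuple[str, Iterable[str]]],
        membrane_sources: Sequence[tuple[str, Iterable[str]]],
    ) -> "AnnotationCatalog":
        return cls(
            secretory=merge_annotation_lists(secretory_sources),
            membrane=merge_annotation_lists(membrane_sources),
        )


def normalize_gene_id(gene_id: str) -> str:
    """Canonical identifier form: trimmed, upper-case."""
    return str(gene_id).strip().upper()


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------


def de_select(
    records: pd.DataFrame | Iterable[DERecord],
    p_max: float = DEFAULT_DE_P_MAX,
    logfc_min: float = DEFAULT_LOGFC_MIN,
    use_abs_logfc: bool = False,
) -> dict[str, set[str]]:
    """Per-experiment DE gene sets at p < p_max and logFC > logfc_min.

    Both inequalities are strict; fold change is signed (up in cancer)
    unless ``use_abs_logfc``.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([vars(r) for r in records])
    if records.empty:
        return {}
    required = {"gene_id", "p_value", "log_fc", "experiment_id"}
    if not required <= set(records.columns):
        raise ValidationError(f"DE table needs columns {sorted(required)}")
    fc = records["log_fc"].abs() if use_abs_logfc else records["log_fc"]
    passing = records[(records["p_value"] < p_max) & (fc > logfc_min)]
    out: dict[str, set[str]] = {str(e): set() for e in records["experiment_id"].unique()}
    for exp, group in passing.groupby("experiment_id"):
        out[str(exp)] = {normalize_gene_id(g) for g in group["gene_id"]}
    return out


def cross_reference(
    est_candidates: Iterable[str],
    per_experiment_de: Mapping[str, Iterable[str]] | Sequence[Iterable[str]],
) -> tuple[set[str], dict[str, list[str]]]:
    """Union over experiments of (EST candidates ∩ experiment DE set).

    Returns the supported gene set plus, per gene, the list of experiments
    that contributed it. Output is always a subset of ``est_candidates``
    and grows monotonically in either argument.
    """
    candidates = {normalize_gene_id(g) for g in est_candidates}
    if isinstance(per_experiment_de, Mapping):
        items = list(per_experiment_de.items())
    else:
        items = [(f"experiment_{i + 1}", genes) for i, genes in enumerate(per_experiment_de)]
    if not items:
        raise ValidationError("need at least one microarray experiment set")
    if not candidates:
        logger.warning("cross_reference called with an empty candidate set")
    support: dict[str, list[str]] = {}
    for exp_id, genes in items:
        hit = candidates & {normalize_gene_id(g) for g in genes}
        for gene in sorted(hit):
            support.setdefault(gene, []).append(str(exp_id))
    return set(support), support


def merge_annotation_lists(
    sources: Sequence[tuple[str, Iterable[str]]],
) -> dict[str, list[str]]:
    """Union of per-source gene lists with provenance.

    Identifiers are normalized (case, whitespace) before the union, so the
    same gene in different letter case collapses to one entry whose
    provenance lists every contributing source. Order-independent up to
    provenance list order (sources are recorded sorted).
    """
    if not sources:
        raise ValidationError("need at least one annotation source")
    merged: dict[str, set[str]] = {}
    for source_name, genes in sources:
        genes = [normalize_gene_id(g) for g in genes if str(g).strip()]
        if not genes:
            logger.warning("annotation source %r contributes no genes", source_name)
        for gene in genes:
            merged.setdefault(gene, set()).add(str(source_name))
    return {gene: sorted(srcs) for gene, srcs in sorted(merged.items())}


def annotate_localization(
    genes: Iterable[str], catalog: AnnotationCatalog
) -> dict[str, str]:
    """Four-way localization tag per gene (a partition of the input)."""
    out: dict[str, str] = {}
    for gene in genes:
        key = normalize_gene_id(gene)
        sec = key in catalog.secretory
        mem = key in catalog.membrane
        if sec and mem:
            out[gene] = "both"
        elif sec:
            out[gene] = "secretory_only"
        elif mem:
            out[gene] = "membrane_only"
        else:
            out[gene] = "neither"
    return out


def localization_counts(localization: Mapping[str, str]) -> dict[str, int]:
    counts = {cat: 0 for cat in LOCALIZATIONS}
    for cat in localization.values():
        counts[cat] += 1
    return counts


def build_candidates(
    est_results: pd.DataFrame,
    de_tables: pd.DataFrame | Iterable[DERecord],
    catalog: AnnotationCatalog | None = None,
    p_max: float = DEFAULT_DE_P_MAX,
    logfc_min: float = DEFAULT_LOGFC_MIN,
    use_abs_logfc: bool = False,
) -> pd.DataFrame:
    """Full cascade: selected EST genes -> microarray support -> localization.

    ``est_results`` is the per-gene results table from the stratified sweep
    (must carry ``gene`` and ``selected``). Returns the supported subset
    joined with supports and (if a catalog is given) localization tags.
    """
    if "gene" not in est_results.columns or "selected" not in est_results.columns:
        raise ValidationError("est_results must carry 'gene' and 'selected'")
    selected = est_results[est_results["selected"].astype(bool)]
    candidate_map = {normalize_gene_id(g): g for g in selected["gene"]}
    per_exp = de_select(de_tables, p_max=p_max, logfc_min=logfc_min,
                        use_abs_logfc=use_abs_logfc)
    supported, support = cross_reference(candidate_map, per_exp)
    out = selected[selected["gene"].map(lambda g: normalize_gene_id(g) in supported)].copy()
    out["supporting_experiments"] = out["gene"].map(
        lambda g: ";".join(support[normalize_gene_id(g)])
    )
    if catalog is not None:
        tags = annotate_localization(out["gene"], catalog)
        out["localization"] = out["gene"].map(tags)
    return out.reset_index(drop=True)


# --------------------------------------------------------------------------
# IO
# --------------------------------------------------------------------------


def read_de_table(path: str | Path, experiment_id: str | None = None) -> pd.DataFrame:
    """TSV with columns gene_id, p_value, log_fc[, experiment_id]."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "p_value", "log_fc"}
    if not required <= set(df.columns):
        raise ValidationError(f"{path}: DE table needs columns {sorted(required)}")
    if "experiment_id" not in df.columns:
        df["experiment_id"] = experiment_id or Path(path).stem
    return df


def read_gene_list(path: str | Path) -> list[str]:
    """One-gene-per-line text or 2-column (gene, source) TSV."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        genes.append(line.split("\t")[0].strip())
    return genes
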