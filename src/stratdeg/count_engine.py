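"""Gene x (tissue, condition) count matrices and the tissue-depth cutoff.

The count matrix is the pipeline's central object: nonnegative integer EST
counts per gene per (tissue, condition) stratum, pooled over all retained
libraries of that stratum. Tissues whose total assigned-EST depth does not
exceed a cutoff (20,000 by default) are kept in storage but excluded from
the downstream stratified analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import CONDITIONS, DEFAULT_MIN_TISSUE_TOTAL
from .errors import ValidationError
from .library_curation import CurationDecision


@dataclass
class CountMatrix:
    """EST counts per gene per (tissue, condition) stratum.

    ``counts`` has shape (genes, tissues, 2) with condition axis ordered
    (normal, cancer). ``retained_tissues`` is None before the depth cutoff
    has been applied, afterwards the subset of tissues entering analysis.
    """

    genes: list[str]
    tissues: list[str]
    counts: np.ndarray
    retained_tissues: list[str] | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        expected = (len(self.genes), len(self.tissues), 2)
        if self.counts.shape != expected:
            raise ValidationError(
                f"counts shape {self.counts.shape} != {expected}"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValidationError("counts must be nonnegative")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene ids")
        if len(set(self.tissues)) != len(self.tissues):
            raise ValidationError("duplicate tissues")
        if self.retained_tissues is not None:
            unknown = set(self.retained_tissues) - set(self.tissues)
            if unknown:
                raise ValidationError(f"unknown retained tissues: {sorted(unknown)}")

    # -- indexing -----------------------------------------------------------

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.genes.index(gene_id)
        except ValueError:
            raise ValidationError(f"unknown gene {gene_id!r}") from None

    def tissue_index(self, tissue: str) -> int:
        try:
            return self.tissues.index(tissue)
        except ValueError:
            raise ValidationError(f"unknown tissue {tissue!r}") from None

    # -- totals -------------------------------------------------------------

    def tissue_totals(self) -> pd.Series:
        """Total counts per tissue, summed over genes and both conditions."""
        return pd.Series(self.counts.sum(axis=(0, 2)), index=self.tissues)

    def stratum_totals(self) -> np.ndarray:
        """(tissues, 2) column totals per (tissue, condition)."""
        return self.counts.sum(axis=0)

    def condition_totals(self) -> np.ndarray:
        """(genes, 2) marginal counts per gene over all tissues."""
        return self.counts.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def analysis_tissues(self) -> list[str]:
        """Tissues entering the stratified analysis (all if cutoff unset)."""
        return list(self.tissues if self.retained_tissues is None else self.retained_tissues)

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Interchange layout: condition marginals then per-tissue pairs."""
        data: dict[str, np.ndarray] = {
            "normal_total": self.counts[:, :, 0].sum(axis=1),
            "cancer_total": self.counts[:, :, 1].sum(axis=1),
        }
        for t_i, tissue in enumerate(self.tissues):
            for c_i, cond in enumerate(CONDITIONS):
                data[f"{tissue}|{cond}"] = self.counts[:, t_i, c_i]
        return pd.DataFrame(data, index=pd.Index(self.genes, name="gene"))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        tissue_cols = [c for c in frame.columns if "|" in c]
        tissues: list[str] = []
        for col in tissue_cols:
            t = col.rsplit("|", 1)[0]
            if t not in tissues:
                tissues.append(t)
        for t in tissues:
            for cond in CONDITIONS:
                if f"{t}|{cond}" not in frame.columns:
                    raise ValidationError(f"missing column {t}|{cond}")
        genes = [str(g) for g in frame.index]
        counts = np.zeros((len(genes), len(tissues), 2), dtype=np.int64)
        for t_i, t in enumerate(tissues):
            for c_i, cond in enumerate(CONDITIONS):
                counts[:, t_i, c_i] = frame[f"{t}|{cond}"].to_numpy()
        return cls(genes=genes, tissues=tissues, counts=counts)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(frame)


# --------------------------------------------------------------------------
# Tabulation
# --------------------------------------------------------------------------


def tabulate_counts(
    gene_library_counts: pd.DataFrame,
    decisions: Sequence[CurationDecision],
    tissues: Sequence[str] | None = None,
) -> CountMatrix:
    """Aggregate per-library gene counts into a CountMatrix.

    Every library referenced by ``gene_library_counts`` must have a retained
    CurationDecision; a count against a discarded or unknown library is an
    error (filter upstream if that is intended). Tissue order is
    alphabetical unless ``tissues`` pins it.
    """
    required = {"gene_id", "library_id", "count"}
    if not required <= set(gene_library_counts.columns):
        raise ValidationError(f"count table needs columns {sorted(required)}")
    retained = {d.library_id: d for d in decisions if d.retained}
    known = {d.library_id for d in decisions}
    refs = set(gene_library_counts["library_id"].unique())
    unknown = sorted(refs - known)
    if unknown:
        raise ValidationError(f"counts reference unknown libraries: {unknown[:10]}")
    discarded = sorted(refs - set(retained))
    if discarded:
        raise ValidationError(f"counts reference discarded libraries: {discarded[:10]}")

    if tissues is None:
        tissues = sorted({d.tissue for d in retained.values()})
    tissues = list(tissues)
    genes = sorted(gene_library_counts["gene_id"].unique())
    g_idx = {g: i for i, g in enumerate(genes)}
    t_idx = {t: i for i, t in enumerate(tissues)}
    c_idx = {c: i for i, c in enumerate(CONDITIONS)}

    counts = np.zeros((len(genes), len(tissues), 2), dtype=np.int64)
    gi = gene_library_counts["gene_id"].map(g_idx).to_numpy()
    dec = gene_library_counts["library_id"].map(retained)
    ti = dec.map(lambda d: t_idx[d.tissue]).to_numpy()
    ci = dec.map(lambda d: c_idx[d.condition]).to_numpy()
    np.add.at(counts, (gi, ti, ci), gene_library_counts["count"].to_numpy())
    return CountMatrix(genes=genes, tissues=tissues, counts=counts)


def apply_tissue_cutoff(
    matrix: CountMatrix, min_tissue_total: int = DEFAULT_MIN_TISSUE_TOTAL
) -> CountMatrix:
    """Mark tissues whose total depth is strictly above the cutoff.

    Non-retained tissues stay in storage (their counts are preserved) but
    are excluded from stratified analysis. Idempotent; raising the cutoff
    never enlarges the retained set.
    """
    totals = matrix.tissue_totals()
    retained = [t for t in matrix.tissues if totals[t] > min_tissue_total]
    if not retained:
        raise ValidationError(
            f"no tissue exceeds the depth cutoff {min_tissue_total}; "
            "lower --min-tissue-total"
        )
    return replace(matrix, counts=matrix.counts.copy(), retained_tissues=retained)
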