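"""EST-to-gene assignment from BLAT alignments.

Each EST keeps its single best transcript hit at >= 95% identity over an
aligned span of >= 100 nt; exact identity ties go to the hit encountered
first in the alignment file. Transcript variants of the same gene are then
pooled into per-gene, per-library counts.

Percent identity is not defined by the PSL format itself; the default here
is ``100 * matches / aligned_span`` with the aligned span the sum of block
sizes, and ``matches / (matches + mismatches)`` available as an alternative.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

from .config import DEFAULT_MIN_ALIGNED_LENGTH, DEFAULT_MIN_IDENTITY
from .errors import ParseError, ValidationError

# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentHit:
    """One EST-to-transcript alignment (PSL summary level)."""

    est_id: str
    transcript_id: str
    matches: int
    mismatches: int
    aligned_length: int
    encounter_rank: int

    def __post_init__(self):
        if self.aligned_length < self.matches:
            raise ValidationError(
                f"hit {self.est_id}->{self.transcript_id}: "
                "aligned_length must be >= matches"
            )


@dataclass(frozen=True)
class GeneAssignment:
    est_id: str
    transcript_id: str
    gene_id: str
    library_id: str


# --------------------------------------------------------------------------
# PSL reading
# --------------------------------------------------------------------------

PSL_COLUMNS = (
    "matches", "misMatches", "repMatches", "nCount", "qNumInsert",
    "qBaseInsert", "tNumInsert", "tBaseInsert", "strand", "qName", "qSize",
    "qStart", "qEnd", "tName", "tSize", "tStart", "tEnd", "blockCount",
    "blockSizes", "qStarts", "tStarts",
)


def read_psl(source: str | Path | TextIO) -> pd.DataFrame:
    """Read a standard 21-column PSL file, with or without psLayout header."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    # skip the optional 5-line psLayout header (banner, labels x2, dashes)
    start = 0
    if lines and lines[0].startswith("psLayout"):
        for i, line in enumerate(lines[:10]):
            if set(line.strip()) <= {"-"} and line.strip():
                start = i + 1
                break
        else:
            raise ParseError("psLayout header without '---' separator line")
    rows = [line.split("\t") for line in lines[start:] if line.strip()]
    if not rows:
        raise ParseError("empty PSL stream")
    bad = [i for i, r in enumerate(rows) if len(r) != 21]
    if bad:
        raise ParseError(f"PSL rows with wrong column count at indices {bad[:5]}")
    df = pd.DataFrame(rows, columns=list(PSL_COLUMNS))
    for col in ("matches", "misMatches", "repMatches", "nCount", "blockCount"):
        df[col] = df[col].astype(np.int64)
    return df


def hits_from_psl(psl: pd.DataFrame) -> pd.DataFrame:
    """Summarize PSL rows into the hit table used for assignment.

    Columns: est_id, transcript_id, matches, mismatches, aligned_length,
    encounter_rank (file order).
    """
    block_sizes = psl["blockSizes"].astype(str).str.rstrip(",").str.split(",")
    aligned = block_sizes.map(lambda parts: sum(int(p) for p in parts if p))
    return pd.DataFrame({
        "est_id": psl["qName"].astype(str),
        "transcript_id": psl["tName"].astype(str),
        "matches": psl["matches"].astype(np.int64),
        "mismatches": psl["misMatches"].astype(np.int64),
        "aligned_length": aligned.astype(np.int64),
        "encounter_rank": np.arange(len(psl), dtype=np.int64),
    })


# --------------------------------------------------------------------------
# Identity and best-hit selection
# --------------------------------------------------------------------------


def percent_identity(hit: AlignmentHit, method: str = "span") -> float:
    """Percent identity of one hit, in [0, 100]."""
    if method == "span":
        if hit.aligned_length == 0:
            raise ValidationError("identity undefined for zero aligned length")
        return 100.0 * hit.matches / hit.aligned_length
    if method == "mismatch":
        denom = hit.matches + hit.mismatches
        if denom == 0:
            raise ValidationError("identity undefined with no aligned bases")
        return 100.0 * hit.matches / denom
    raise ValidationError(f"unknown identity method {method!r}")


def assign_best_hit(
    hits: Sequence[AlignmentHit],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_length: int = DEFAULT_MIN_ALIGNED_LENGTH,
    identity_method: str = "span",
) -> str | None:
    """Best transcript for one EST, or None when no hit passes the filters.

    Identity threshold is inclusive (95.0 passes at the default); ties on
    identity are broken by lowest encounter rank.
    """
    if not hits:
        return None
    est_ids = {h.est_id for h in hits}
    if len(est_ids) > 1:
        raise ValidationError(f"hits span several ESTs: {sorted(est_ids)}")
    best: tuple[float, int] | None = None
    best_transcript: str | None = None
    for h in hits:
        if h.aligned_length < min_length:
            continue
        ident = percent_identity(h, identity_method)
        if ident < min_identity:
            continue
        key = (-ident, h.encounter_rank)
        if best is None or key < best:
            best = key
            best_transcript = h.transcript_id
    return best_transcript


def assign_best_hits(
    hits: pd.DataFrame,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_length: int = DEFAULT_MIN_ALIGNED_LENGTH,
    identity_method: str = "span",
) -> tuple[pd.DataFrame, list[str]]:
    """Vectorized best-hit assignment over a hit table.

    Returns (assignments, unassigned_est_ids); assignments has one row per
    assigned EST with columns est_id, transcript_id, identity.
    """
    required = {"est_id", "transcript_id", "matches", "aligned_length", "encounter_rank"}
    missing = required - set(hits.columns)
    if missing:
        raise ValidationError(f"hit table missing columns: {sorted(missing)}")
    df = hits.copy()
    if identity_method == "span":
        if (df["aligned_length"] == 0).any():
            raise ValidationError("identity undefined for zero aligned length")
        df["identity"] = 100.0 * df["matches"] / df["aligned_length"]
    elif identity_method == "mismatch":
        denom = df["matches"] + df["mismatches"]
        if (denom == 0).any():
            raise ValidationError("identity undefined with no aligned bases")
        df["identity"] = 100.0 * df["matches"] / denom
    else:
        raise ValidationError(f"unknown identity method {identity_method!r}")

    surviving = df[(df["identity"] >= min_identity) & (df["aligned_length"] >= min_length)]
    # highest identity first, then earliest encounter; stable sort for determinism
    ordered = surviving.sort_values(
        ["est_id", "identity", "encounter_rank"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    assignments = ordered.drop_duplicates("est_id")[["est_id", "transcript_id", "identity"]]
    assignments = assignments.reset_index(drop=True)
    all_ests = pd.unique(df["est_id"])
    assigned = set(assignments["est_id"])
    unassigned = [e for e in all_ests if e not in assigned]
    return assignments, unassigned


# --------------------------------------------------------------------------
# Variant pooling
# --------------------------------------------------------------------------


def collapse_to_genes(
    assignments: pd.DataFrame | Iterable[GeneAssignment],
    transcript_to_gene: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Pool transcript-level assignments into per-gene per-library counts.

    ``assignments`` must carry est_id, transcript_id and library_id (a
    ``gene_id`` column is honored if already present and no map is given).
    Returns a DataFrame (gene_id, library_id, count); total EST count is
    conserved. Transcripts with no gene mapping raise, listing offenders.
    """
    if not isinstance(assignments, pd.DataFrame):
        assignments = pd.DataFrame([vars(a) for a in assignments])
    if assignments.empty:
        return pd.DataFrame(columns=["gene_id", "library_id", "count"])
    df = assignments.copy()
    if transcript_to_gene is not None:
        mapped = df["transcript_id"].map(transcript_to_gene)
        unmapped = sorted(df.loc[mapped.isna(), "transcript_id"].unique())
        if unmapped:
            raise ValidationError(
                f"{len(unmapped)} transcript(s) with no gene mapping: {unmapped[:10]}"
            )
        df["gene_id"] = mapped
    elif "gene_id" not in df.columns:
        raise ValidationError("need a transcript_to_gene map or a gene_id column")
    counts = (
        df.groupby(["gene_id", "library_id"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return counts


def attach_libraries(assignments: pd.DataFrame, est_library: Mapping[str, str] | pd.DataFrame) -> pd.DataFrame:
    """Join each assigned EST with its source library id."""
    if isinstance(est_library, pd.DataFrame):
        est_library = dict(zip(est_library["est_id"], est_library["library_id"]))
    out = assignments.copy()
    out["library_id"] = out["est_id"].map(est_library)
    missing = sorted(out.loc[out["library_id"].isna(), "est_id"].unique())
    if missing:
        raise ValidationError(f"ESTs with unknown source library: {missing[:10]}")
    return out


def read_gene_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (transcript accession -> gene symbol), no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["transcript_id", "gene_id"], dtype=str)
    if df.empty:
        raise ParseError(f"empty gene map: {path}")
    return dict(zip(df["transcript_id"], df["gene_id"]))
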