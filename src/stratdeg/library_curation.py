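"""EST clone-library curation.

cDNA libraries from dbEST/CGAP-style reports are screened before counting:
libraries whose preparation distorts transcript abundance (normalization,
subtraction, PCR amplification, enrichment), libraries made from cell lines
or mixed tissues, and very small libraries are discarded. Surviving
libraries are mapped onto a canonical tissue vocabulary (48 tissues by
default) and a condition (normal vs cancer). Every discard reason that
applies is recorded, not just the first.
"""
from __future__ import annotations

import csv
import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

from .config import DEFAULT_EXCLUSION_KEYWORDS, DEFAULT_MIN_LIBRARY_ESTS
from .errors import ParseError, ValidationError

# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LibraryRecord:
    """Metadata for one EST clone library."""

    library_id: str
    title: str = ""
    descr: str = ""
    unique_protocol: str = ""
    keywords: str = ""
    tissue_label: str = ""
    histology_label: str = ""
    est_count: int = 0
    is_cell_line: bool = False
    is_mixed_tissue: bool = False

    def __post_init__(self):
        if self.est_count < 0:
            raise ValidationError(
                f"library {self.library_id}: est_count must be >= 0"
            )


@dataclass(frozen=True)
class CurationDecision:
    """Retain/discard verdict for one library, with reasons."""

    library_id: str
    retained: bool
    reasons: tuple[str, ...] = ()
    tissue: str = ""
    condition: str = ""

    def __post_init__(self):
        if self.retained and self.reasons:
            raise ValidationError("retained decision must have no reasons")
        if self.retained and not (self.tissue and self.condition):
            raise ValidationError("retained decision needs tissue + condition")
        if not self.retained and not self.reasons:
            raise ValidationError("discarded decision needs >= 1 reason")


@dataclass
class ParseIssue:
    """A recoverable problem found while parsing one library block/row."""

    location: str
    message: str


# --------------------------------------------------------------------------
# Canonical tissue vocabulary (48 tissues) and condition mapping
# --------------------------------------------------------------------------

DEFAULT_TISSUES: tuple[str, ...] = (
    "adipose", "adrenal gland", "bladder", "blood", "bone", "bone marrow",
    "brain", "breast", "cartilage", "cervix", "colon", "connective tissue",
    "ear", "embryo", "esophagus", "eye", "gallbladder", "head and neck",
    "heart", "intestine", "kidney", "larynx", "liver", "lung", "lymph node",
    "mammary gland", "muscle", "nerve", "ovary", "pancreas", "parathyroid",
    "pituitary", "placenta", "prostate", "retina", "salivary gland", "skin",
    "spinal cord", "spleen", "stomach", "synovium", "testis", "thymus",
    "thyroid", "tongue", "tonsil", "trachea", "uterus",
)

#: Extra raw-label aliases on top of the identity (lower-cased) mapping.
_TISSUE_ALIASES: dict[str, str] = {
    "cerebrum": "brain", "cerebellum": "brain", "whole brain": "brain",
    "large intestine": "colon", "colorectal": "colon",
    "small intestine": "intestine",
    "marrow": "bone marrow",
    "skeletal muscle": "muscle",
    "peripheral nerve": "nerve",
    "lymphnode": "lymph node",
    "adrenal": "adrenal gland",
    "salivary": "salivary gland",
    "mammary": "mammary gland",
    "womb": "uterus", "endometrium": "uterus",
    "oesophagus": "esophagus",
}

_CANCER_WORDS = (
    "cancer", "carcinoma", "adenocarcinoma", "tumor", "tumour", "malignan",
    "sarcoma", "leukemia", "leukaemia", "lymphoma", "glioma", "blastoma",
    "melanoma", "neoplas", "metasta",
)
_NORMAL_WORDS = ("normal", "non-neoplastic", "healthy", "benign")


def default_tissue_vocab(tissues: Sequence[str] = DEFAULT_TISSUES) -> dict[str, str]:
    """Raw tissue label (case-folded) -> canonical tissue name."""
    vocab = {t.casefold(): t for t in tissues}
    for alias, canonical in _TISSUE_ALIASES.items():
        if canonical in tissues:
            vocab[alias.casefold()] = canonical
    return vocab


def classify_condition(histology_label: str) -> str:
    """Map a raw histology label to 'normal', 'cancer' or '' (unknown).

    Cancer words win over normal words except for explicitly benign lesions.
    """
    text = histology_label.casefold()
    if not text:
        return ""
    if "benign" in text:
        return "normal"
    if any(w in text for w in _CANCER_WORDS):
        return "cancer"
    if any(w in text for w in _NORMAL_WORDS):
        return "normal"
    return ""


# --------------------------------------------------------------------------
# Parsing
# --------------------------------------------------------------------------

#: Field labels of the labeled-block ("dbest"-style) dialect.
DBEST_LABELS: dict[str, str] = {
    "library_id": "LIBRARY_ID",
    "title": "TITLE",
    "descr": "DESCR",
    "unique_protocol": "UNIQUE_PROTOCOL",
    "keywords": "KEYWORDS",
    "tissue_label": "TISSUE",
    "histology_label": "HISTOLOGY",
    "est_count": "EST_COUNT",
    "is_cell_line": "CELL_LINE",
    "is_mixed_tissue": "MIXED_TISSUE",
}

TSV_COLUMNS = (
    "library_id", "descr", "unique_protocol", "keywords", "tissue_label",
    "histology_label", "est_count", "is_cell_line", "is_mixed_tissue",
)

_TRUE_WORDS = ("1", "true", "yes", "y")


def parse_library_records(
    source: str | Path | TextIO,
    dialect: str = "dbest",
    labels: Mapping[str, str] | None = None,
) -> tuple[list[LibraryRecord], list[ParseIssue]]:
    """Parse library metadata from a labeled-block report or a TSV table.

    Malformed blocks/rows and duplicate library ids are collected as
    :class:`ParseIssue` entries and parsing continues; an empty stream is a
    hard :class:`ParseError`.
    """
    text = _read_text(source)
    if not text.strip():
        raise ParseError("empty library metadata stream")
    if dialect == "dbest":
        return _parse_blocks(text, dict(labels or DBEST_LABELS))
    if dialect == "tsv":
        return _parse_tsv(text)
    raise ParseError(f"unknown library dialect: {dialect!r}")


def _read_text(source: str | Path | TextIO) -> str:
    if hasattr(source, "read"):
        return source.read()
    text = str(source)
    if "\n" in text or "\t" in text:
        return text  # raw report text, not a path
    path = Path(source)
    if path.exists():
        return path.read_text()
    return text


def _parse_blocks(text: str, labels: dict[str, str]) -> tuple[list[LibraryRecord], list[ParseIssue]]:
    label_to_field = {v.casefold(): k for k, v in labels.items()}
    records: list[LibraryRecord] = []
    issues: list[ParseIssue] = []
    seen: set[str] = set()
    blocks = [b for b in text.split("\n\n") if b.strip()]
    for bi, block in enumerate(blocks, start=1):
        fields: dict[str, str] = {}
        current: str | None = None
        for line in block.splitlines():
            if not line.strip():
                continue
            if line[:1].isspace() and current is not None:
                fields[current] += " " + line.strip()  # continuation line
                continue
            key, sep, value = line.partition(":")
            if not sep:
                issues.append(ParseIssue(f"block {bi}", f"unlabeled line: {line.strip()!r}"))
                current = None
                continue
            fname = label_to_field.get(key.strip().casefold())
            if fname is None:
                current = None  # unknown label: ignored
                continue
            fields[fname] = value.strip()
            current = fname
        record, issue = _build_record(fields, f"block {bi}", seen)
        if record is not None:
            records.append(record)
        if issue is not None:
            issues.append(issue)
    return records, issues


def _parse_tsv(text: str) -> tuple[list[LibraryRecord], list[ParseIssue]]:
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    if reader.fieldnames is None or "library_id" not in reader.fieldnames:
        raise ParseError("library TSV must have a header with 'library_id'")
    records: list[LibraryRecord] = []
    issues: list[ParseIssue] = []
    seen: set[str] = set()
    for i, row in enumerate(reader, start=2):
        fields = {k: (row.get(k) or "") for k in TSV_COLUMNS}
        record, issue = _build_record(fields, f"line {i}", seen)
        if record is not None:
            records.append(record)
        if issue is not None:
            issues.append(issue)
    return records, issues


def _build_record(fields: dict[str, str], location: str, seen: set[str]):
    lib_id = fields.get("library_id", "").strip()
    if not lib_id:
        return None, ParseIssue(location, "missing library_id")
    if lib_id in seen:
        return None, ParseIssue(location, f"duplicate library_id {lib_id!r}")
    raw_count = str(fields.get("est_count", "") or "").strip()
    try:
        est_count = int(raw_count) if raw_count else 0
    except ValueError:
        return None, ParseIssue(location, f"bad est_count {raw_count!r}")
    record = LibraryRecord(
        library_id=lib_id,
        title=fields.get("title", ""),
        descr=fields.get("descr", ""),
        unique_protocol=fields.get("unique_protocol", ""),
        keywords=fields.get("keywords", ""),
        tissue_label=fields.get("tissue_label", ""),
        histology_label=fields.get("histology_label", ""),
        est_count=est_count,
        is_cell_line=str(fields.get("is_cell_line", "")).strip().lower() in _TRUE_WORDS,
        is_mixed_tissue=str(fields.get("is_mixed_tissue", "")).strip().lower() in _TRUE_WORDS,
    )
    seen.add(lib_id)
    return record, None


# --------------------------------------------------------------------------
# Curation
# --------------------------------------------------------------------------


def curate_libraries(
    records: Sequence[LibraryRecord],
    exclusion_keywords: Sequence[str] = DEFAULT_EXCLUSION_KEYWORDS,
    min_est_count: int = DEFAULT_MIN_LIBRARY_ESTS,
    tissue_vocab: Mapping[str, str] | None = None,
    overrides: Mapping[str, CurationDecision] | None = None,
) -> list[CurationDecision]:
    """Apply the exclusion rules and classify retained libraries.

    A library is discarded when (i) any exclusion keyword occurs
    case-insensitively as a substring of DESCR, UNIQUE_PROTOCOL or KEYWORDS;
    (ii) it derives from a cell line or mixed tissue; (iii) its EST count is
    <= ``min_est_count``; or (iv) its tissue or histology label cannot be
    classified. ``overrides`` (library_id -> forced decision) models the
    manual-curation pass and is applied after rule evaluation.
    """
    if not records:
        raise ValidationError("no library records to curate")
    if not exclusion_keywords:
        raise ValidationError("exclusion keyword list must be non-empty")
    vocab = tissue_vocab if tissue_vocab is not None else default_tissue_vocab()
    if not vocab:
        raise ValidationError("tissue vocabulary must be non-empty")
    overrides = overrides or {}

    decisions: list[CurationDecision] = []
    for rec in records:
        if rec.library_id in overrides:
            decisions.append(overrides[rec.library_id])
            continue
        reasons: list[str] = []
        haystack = " ".join((rec.descr, rec.unique_protocol, rec.keywords)).casefold()
        for kw in exclusion_keywords:
            if kw.casefold() in haystack:
                reasons.append(f"keyword_hit:{kw}")
        if rec.is_cell_line:
            reasons.append("cell_line")
        if rec.is_mixed_tissue:
            reasons.append("mixed_tissue")
        if rec.est_count <= min_est_count:
            reasons.append("below_size_cutoff")
        tissue = vocab.get(rec.tissue_label.strip().casefold(), "")
        condition = classify_condition(rec.histology_label)
        if not tissue or not condition:
            reasons.append("unclassifiable")
        if reasons:
            decisions.append(CurationDecision(rec.library_id, False, tuple(reasons)))
        else:
            decisions.append(CurationDecision(rec.library_id, True, (), tissue, condition))
    return decisions


def discard_tally(decisions: Iterable[CurationDecision]) -> Counter:
    """Per-rule discard counts (a library with two reasons counts in both)."""
    tally: Counter = Counter()
    for d in decisions:
        for reason in d.reasons:
            key = reason.split(":", 1)[0] if reason.startswith("keyword_hit") else reason
            tally[key] += 1
    return tally


# --------------------------------------------------------------------------
# IO
# --------------------------------------------------------------------------


def write_curation_tsv(decisions: Sequence[CurationDecision], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["library_id", "retained", "reasons", "tissue", "condition"])
        for d in decisions:
            writer.writerow([
                d.library_id, str(d.retained).lower(), ";".join(d.reasons),
                d.tissue, d.condition,
            ])


def read_curation_tsv(path: str | Path) -> list[CurationDecision]:
    decisions = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            decisions.append(CurationDecision(
                library_id=row["library_id"],
                retained=row["retained"].strip().lower() in _TRUE_WORDS,
                reasons=tuple(r for r in row["reasons"].split(";") if r),
                tissue=row.get("tissue", ""),
                condition=row.get("condition", ""),
            ))
    return decisions


def read_overrides_tsv(path: str | Path) -> dict[str, CurationDecision]:
    """Manual override table: same columns as the curation TSV."""
    return {d.library_id: d for d in read_curation_tsv(path)}
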