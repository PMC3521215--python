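"""Run configuration: every screening threshold in one place.

The defaults are the thresholds of the published EST screening protocol this
package implements: libraries with more than 400 ESTs, alignments at >= 95%
identity over >= 100 nt, tissues with more than 20,000 assigned ESTs, CMH
p < 0.05 with the 95% CI lower bound of the common odds ratio >= 1.65, and
microarray cross-reference at p < 0.05 with log2 fold change > 1.0.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

from .errors import ConfigError

#: Library-description keywords flagging abundance-distorting protocols.
DEFAULT_EXCLUSION_KEYWORDS: tuple[str, ...] = (
    "enrichment", "subtract", "pcr", "normalized",
)

#: Libraries must contain strictly more ESTs than this to be kept.
DEFAULT_MIN_LIBRARY_ESTS = 400
#: BLAT hit acceptance: percent identity (inclusive) and aligned span (nt).
DEFAULT_MIN_IDENTITY = 95.0
DEFAULT_MIN_ALIGNED_LENGTH = 100
#: A tissue enters the stratified analysis only above this assigned-EST depth.
DEFAULT_MIN_TISSUE_TOTAL = 20_000
#: Candidate selection.
DEFAULT_ALPHA = 0.05
DEFAULT_CI_LEVEL = 0.95
DEFAULT_CI_LOWER_MIN = 1.65
#: Microarray cross-reference.
DEFAULT_DE_P_MAX = 0.05
DEFAULT_LOGFC_MIN = 1.0

CONDITIONS: tuple[str, str] = ("normal", "cancer")


@dataclass
class PipelineConfig:
    """Thresholds plus (optional) input/output paths for a full run."""

    # thresholds
    exclusion_keywords: tuple[str, ...] = DEFAULT_EXCLUSION_KEYWORDS
    min_library_ests: int = DEFAULT_MIN_LIBRARY_ESTS
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_aligned_length: int = DEFAULT_MIN_ALIGNED_LENGTH
    min_tissue_total: int = DEFAULT_MIN_TISSUE_TOTAL
    alpha: float = DEFAULT_ALPHA
    ci_level: float = DEFAULT_CI_LEVEL
    ci_lower_min: float = DEFAULT_CI_LOWER_MIN
    continuity_correction: bool = True
    ci_method: str = "rbg"
    de_p_max: float = DEFAULT_DE_P_MAX
    logfc_min: float = DEFAULT_LOGFC_MIN
    seed: int = 0
    # file paths (strings; empty = not provided)
    libraries: str = ""
    overrides: str = ""
    psl: str = ""
    gene_map: str = ""
    est_library: str = ""
    counts: str = ""
    de_tables: tuple[str, ...] = ()
    secretory: tuple[str, ...] = ()
    membrane: tuple[str, ...] = ()
    outdir: str = "stratdeg_out"
    simulate: bool = False
    sim_n_libraries: int = 60
    sim_contamination: float = 0.25
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "PipelineConfig":
        known = {f.name: f for f in fields(cls)}
        kwargs: dict = {}
        extra: dict = {}
        for raw_key, value in mapping.items():
            key = raw_key.strip().lower().replace("-", "_")
            if key not in known:
                extra[key] = value
                continue
            kwargs[key] = _coerce(known[key].type, key, value)
        cfg = cls(**kwargs)
        cfg.extra.update(extra)
        return cfg


def _coerce(annot, key: str, value):
    if isinstance(value, str):
        value = value.strip()
    try:
        if annot in ("int", int):
            return int(value)
        if annot in ("float", float):
            return float(value)
        if annot in ("bool", bool):
            if isinstance(value, bool):
                return value
            return value.lower() in ("1", "true", "yes", "on")
        if str(annot).startswith("tuple") and isinstance(value, str):
            return tuple(v.strip() for v in value.split(",") if v.strip())
    except ValueError as exc:
        raise ConfigError(f"bad value for {key!r}: {value!r}") from exc
    return value


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat ``key = value`` configuration file.

    Lines starting with ``#`` and blank lines are ignored; keys are
    case-insensitive, ``-``/``_`` interchangeable.
    """
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"config file not found: {path}")
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        mapping[key.strip()] = value.strip()
    return PipelineConfig.from_mapping(mapping)


def configure_logging(level: str = "INFO", logfile: str | Path | None = None) -> logging.Logger:
    logger = logging.getLogger("stratdeg")
    logger.setLevel(level.upper())
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    handler: logging.Handler = logging.StreamHandler()
    handler.setFormatter(fmt)
    logger.addHandler(handler)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        logger.addHandler(fh)
    return logger
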