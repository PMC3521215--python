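"""Synthetic EST corpora with known ground truth.

Every pipeline stage is testable offline against generated data: clone
library metadata (with planted contamination), PSL alignment tables
realizing planted per-library gene counts, and gene x (tissue, condition)
count matrices drawn multinomially with controllable per-gene odds ratios.

The default conditions emulate the statistical structure of the curated
2009 dbEST corpus this method was developed on: ~1.64 million assigned
ESTs, 48 tissue types dominated by brain (26%), a roughly 3:1
normal-to-cancer depth ratio, and tissues too shallow for the 20,000-hit
cutoff. Genes are multinomial within each (tissue, condition) stratum; a
gene's cancer proportion is tilted on the odds scale,
``p' = theta * p / (1 - p + theta * p)``, so its true within-stratum odds
ratio against the pooled rest is exactly ``theta`` up to the (tiny)
renormalization over other genes.

Simpson-paradox genes are constructed deterministically in the Table-1
pattern: the gene concentrates in a cancer-oversampled stratum, every
stratum odds ratio sits below 1, yet the pooled odds ratio exceeds 1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .count_engine import CountMatrix
from .errors import InfeasibleParadoxError, ValidationError
from .library_curation import DEFAULT_TISSUES, LibraryRecord
from .stratified_stats import StratifiedTable, StratumTable

# --------------------------------------------------------------------------
# Study-scale defaults
# --------------------------------------------------------------------------

#: Total assigned ESTs in the corpus being emulated.
DEFAULT_TOTAL_DEPTH = 1_644_960
#: Matched-EST share of the most-sampled tissues; the remainder decays.
_NAMED_SHARES = {
    "brain": 0.26, "uterus": 0.064, "testis": 0.0591, "placenta": 0.0433,
    "pancreas": 0.0399, "muscle": 0.0388, "kidney": 0.0352, "liver": 0.0351,
}
#: Overall normal:cancer EST depth ratio is roughly 3:1.
DEFAULT_NORMAL_FRACTION = 0.75

TOP_TISSUES = tuple(_NAMED_SHARES)


def default_tissue_shares(tissues: Sequence[str] = DEFAULT_TISSUES) -> dict[str, float]:
    """Per-tissue share of total EST depth (brain-dominant skew).

    Named tissues take their observed shares; the rest split the remainder
    with a 1/(rank+3) decay so that the shallow tail falls under the
    20,000-hit cutoff at the default total depth.
    """
    shares = {t: s for t, s in _NAMED_SHARES.items() if t in tissues}
    rest = [t for t in tissues if t not in shares]
    if rest:
        w = np.array([1.0 / (i + 3) for i in range(len(rest))])
        w *= (1.0 - sum(shares.values())) / w.sum()
        shares.update(zip(rest, w))
    total = sum(shares.values())
    return {t: s / total for t, s in shares.items()}


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Everything needed to regenerate and to verify a synthetic matrix."""

    seed: int
    genes: list[str]
    tissues: list[str]
    baseline: np.ndarray  # (G, T) per-tissue gene proportions, columns sum to 1
    theta: np.ndarray  # (G, T) true per-gene per-tissue odds ratios
    depths: np.ndarray  # (T, 2) EST totals per stratum, (normal, cancer)
    paradox_counts: dict[str, np.ndarray] = field(default_factory=dict)
    contamination: float = 0.0

    def __post_init__(self):
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.depths = np.asarray(self.depths, dtype=np.int64)
        G, T = len(self.genes), len(self.tissues)
        if self.baseline.shape != (G, T) or self.theta.shape != (G, T):
            raise ValidationError("baseline/theta must be (genes, tissues)")
        if self.depths.shape != (T, 2):
            raise ValidationError("depths must be (tissues, 2)")
        colsums = self.baseline.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-8):
            raise ValidationError("baseline proportions must sum to 1 per tissue")
        if (self.theta <= 0).any():
            raise ValidationError("true odds ratios must be positive")


def make_truth(
    n_genes: int = 2_000,
    tissues: Sequence[str] = DEFAULT_TISSUES,
    total_depth: int = DEFAULT_TOTAL_DEPTH,
    baseline: str = "lognormal",
    theta: Mapping[str, float] | None = None,
    n_paradox_genes: int = 0,
    contamination: float = 0.0,
    seed: int = 0,
    vary_condition_balance: bool = True,
) -> SyntheticTruth:
    """Build a ground truth under the default study conditions.

    ``baseline='lognormal'`` spreads gene abundances realistically (sigma=1
    log-normal); ``'flat'`` makes genes exchangeable, the configuration
    used for test-statistic calibration. ``theta`` maps gene ids to a
    common odds ratio applied in every tissue (all unlisted genes are null,
    theta=1). Condition balance per tissue varies around 3:1 (heart has no
    cancer sampling); ``vary_condition_balance=False`` pins 3:1 everywhere.
    """
    rng = np.random.default_rng(seed)
    tissues = list(tissues)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    paradox = [f"PARADOX{i:03d}" for i in range(n_paradox_genes)]
    all_genes = genes + paradox

    shares = default_tissue_shares(tissues)
    normal_frac = np.full(len(tissues), DEFAULT_NORMAL_FRACTION)
    if vary_condition_balance:
        normal_frac = rng.beta(6.0, 2.0, size=len(tissues))
    for i, t in enumerate(tissues):
        if t == "heart":
            normal_frac[i] = 1.0  # condition-starved stratum by design
    depths = np.zeros((len(tissues), 2), dtype=np.int64)
    for i, t in enumerate(tissues):
        n_t = int(round(total_depth * shares[t]))
        depths[i, 0] = int(round(n_t * normal_frac[i]))
        depths[i, 1] = n_t - depths[i, 0]

    G = len(all_genes)
    if baseline == "flat":
        base = np.full((G, len(tissues)), 1.0 / G)
    elif baseline == "lognormal":
        weights = rng.lognormal(mean=0.0, sigma=1.0, size=G)
        base = np.tile((weights / weights.sum())[:, None], (1, len(tissues)))
    else:
        raise ValidationError(f"unknown baseline scheme {baseline!r}")

    theta_arr = np.ones((G, len(tissues)))
    gene_index = {g: i for i, g in enumerate(all_genes)}
    for gene_id, value in (theta or {}).items():
        if gene_id not in gene_index:
            raise ValidationError(f"theta for unknown gene {gene_id!r}")
        theta_arr[gene_index[gene_id], :] = value

    truth = SyntheticTruth(
        seed=seed, genes=all_genes, tissues=tissues, baseline=base,
        theta=theta_arr, depths=depths, contamination=contamination,
    )
    if paradox:
        _plant_paradox_genes(truth, paradox, rng)
    return truth


def _plant_paradox_genes(truth: SyntheticTruth, paradox: list[str], rng) -> None:
    """Assign each paradox gene deterministic Table-1-style counts.

    The gene is concentrated in the most cancer-oversampled usable tissue
    and sparsely present in the most normal-oversampled one; both strata
    get odds ratios below 1 while the corpus-wide pooled table reverses.
    """
    usable = np.where((truth.depths[:, 0] >= 1_000) & (truth.depths[:, 1] >= 1_000))[0]
    if len(usable) < 2:
        raise InfeasibleParadoxError(
            "paradox planting needs >= 2 tissues sampled in both conditions"
        )
    cancer_frac = truth.depths[usable, 1] / truth.depths[usable].sum(axis=1)
    hi = int(usable[np.argmax(cancer_frac)])  # most cancer-skewed
    lo = int(usable[np.argmin(cancer_frac)])  # most normal-skewed
    total_n, total_c = int(truth.depths[:, 0].sum()), int(truth.depths[:, 1].sum())
    depths = [tuple(truth.depths[hi]), tuple(truth.depths[lo])]
    gidx = {g: i for i, g in enumerate(truth.genes)}
    for gene in paradox:
        table = None
        for _ in range(200):
            psi = rng.uniform(0.55, 0.85, size=2)
            r_hi = rng.uniform(0.008, 0.02)
            # keep every cell of the sparse stratum >= ~4 counts
            r_lo = max(8.0 / truth.depths[lo, 0], 8.0 / (psi[1] * truth.depths[lo, 1]))
            try:
                table = generate_paradox_gene(
                    depths, list(psi), [r_hi, r_lo],
                    background_depths=(total_n, total_c),
                )
                break
            except InfeasibleParadoxError:
                continue
        if table is None:
            raise InfeasibleParadoxError(
                "no valid paradox construction for the configured depths"
            )
        counts = np.zeros((len(truth.tissues), 2), dtype=np.int64)
        counts[hi] = (table.strata[0].b, table.strata[0].a)
        counts[lo] = (table.strata[1].b, table.strata[1].a)
        truth.paradox_counts[gene] = counts
        truth.baseline[gidx[gene], :] = 0.0
    # renormalize the remaining genes' proportions per tissue
    truth.baseline /= truth.baseline.sum(axis=0)


# --------------------------------------------------------------------------
# Count-matrix generation
# --------------------------------------------------------------------------


def tilt_proportions(baseline: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Odds-tilted, renormalized cancer proportions for one stratum."""
    tilted = theta * baseline / (1.0 - baseline + theta * baseline)
    total = tilted.sum()
    if total <= 0:
        raise ValidationError("degenerate tilted proportions")
    return tilted / total


def generate_count_matrix(
    truth: SyntheticTruth, rng: np.random.Generator | None = None
) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw a CountMatrix from the truth (multinomial per stratum).

    Paradox genes receive their constructed counts exactly; the remaining
    stratum depth is distributed multinomially over the other genes, so
    stratum totals equal ``truth.depths`` by construction. Reproducible:
    the default generator is seeded from ``truth.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed + 1)
    G, T = len(truth.genes), len(truth.tissues)
    counts = np.zeros((G, T, 2), dtype=np.int64)
    paradox_idx = {g: truth.genes.index(g) for g in truth.paradox_counts}
    free = np.ones(G, dtype=bool)
    for g in paradox_idx.values():
        free[g] = False
    for t in range(T):
        planted = np.zeros(2, dtype=np.int64)
        for gene, planted_counts in truth.paradox_counts.items():
            g = paradox_idx[gene]
            counts[g, t, :] = planted_counts[t]
            planted += planted_counts[t]
        for ci in range(2):
            depth = int(truth.depths[t, ci]) - int(planted[ci])
            if depth < 0:
                raise ValidationError(
                    f"planted counts exceed stratum depth in tissue {truth.tissues[t]}"
                )
            base = truth.baseline[free, t]
            if base.sum() <= 0:
                if depth:
                    raise ValidationError("no free proportion mass to sample from")
                continue
            p = base / base.sum()
            if ci == 1:
                p = tilt_proportions(p, truth.theta[free, t])
            counts[free, t, ci] = rng.multinomial(depth, p)
    matrix = CountMatrix(genes=list(truth.genes), tissues=list(truth.tissues), counts=counts)
    return matrix, truth


def null_sweep_matrix(
    n_genes: int = 10_000,
    seed: int = 0,
    total_depth: int = 1_600_000,
    tissues: Sequence[str] = TOP_TISSUES,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Calibration scenario: exchangeable null genes over the deep tissues.

    Flat baseline, theta = 1 everywhere, fixed 3:1 condition balance —
    the configuration for checking the sweep's type-I error.
    """
    truth = make_truth(
        n_genes=n_genes, tissues=tissues, total_depth=total_depth,
        baseline="flat", seed=seed, vary_condition_balance=False,
    )
    matrix, _ = generate_count_matrix(truth)
    matrix.retained_tissues = list(matrix.tissues)
    return matrix, truth


def simulate_focal_tables(
    theta: float,
    n_reps: int,
    rng: np.random.Generator,
    n_strata: int = 8,
    stratum_depth: tuple[int, int] = (30_000, 10_000),
    focal_rate: float = 0.005,
) -> list[StratifiedTable]:
    """Replicate 2x2xk tables for one focal gene with true common OR theta.

    Per stratum the focal count is binomial: rate ``focal_rate`` among
    normal ESTs and the odds-tilted rate among cancer ESTs, so the true
    conditional odds ratio is exactly ``theta`` in every stratum.
    """
    n_n, n_c = stratum_depth
    p = focal_rate
    p_c = theta * p / (1 - p + theta * p)
    b = rng.binomial(n_n, p, size=(n_reps, n_strata))
    a = rng.binomial(n_c, p_c, size=(n_reps, n_strata))
    tables = []
    for r in range(n_reps):
        strata = tuple(
            StratumTable(
                tissue=f"T{s:02d}", a=int(a[r, s]), b=int(b[r, s]),
                c=n_c - int(a[r, s]), d=n_n - int(b[r, s]),
            )
            for s in range(n_strata)
        )
        tables.append(StratifiedTable(gene_id=f"rep{r}", strata=strata))
    return tables


# --------------------------------------------------------------------------
# Simpson-paradox construction
# --------------------------------------------------------------------------


def generate_paradox_gene(
    stratum_depths: Sequence[tuple[int, int]],
    stratum_odds_ratios: Sequence[float],
    gene_normal_rates: Sequence[float],
    mirror: bool = False,
    background_depths: tuple[int, int] | None = None,
) -> StratifiedTable:
    """Construct a gene whose pooled OR and stratum ORs disagree in sign.

    ``stratum_depths`` are (normal_total, cancer_total) column totals per
    stratum, including the gene; each stratum's odds ratio is set to the
    requested value (< 1 unless ``mirror``) through the gene's normal-EST
    rate. ``background_depths`` adds extra (normal, cancer) depth from
    strata where the gene is absent to the pooled check, matching the
    situation of a gene concentrated in few tissues of a larger corpus.
    The construction is validated on the resulting integer table; an
    impossible configuration (e.g. balanced sampling between strata)
    raises :class:`InfeasibleParadoxError`.
    """
    if len(stratum_depths) < 2:
        raise InfeasibleParadoxError("need >= 2 strata with opposing imbalance")
    if not (len(stratum_depths) == len(stratum_odds_ratios) == len(gene_normal_rates)):
        raise InfeasibleParadoxError("depths, odds ratios and rates must align")
    strata = []
    for i, ((n_n, n_c), psi, rate) in enumerate(
        zip(stratum_depths, stratum_odds_ratios, gene_normal_rates)
    ):
        if psi <= 0 or not 0 < rate < 1:
            raise InfeasibleParadoxError("need psi > 0 and 0 < rate < 1")
        b = int(round(n_n * rate))
        rate_c = psi * rate / (1 - rate + psi * rate)
        a = int(round(n_c * rate_c))
        c, d = n_c - a, n_n - b
        if min(a, b, c, d) < 1:
            raise InfeasibleParadoxError(
                f"stratum {i}: empty cell at these depths/rates"
            )
        strata.append(StratumTable(tissue=f"S{i:02d}", a=a, b=b, c=c, d=d))
    if mirror:
        strata = [
            StratumTable(tissue=s.tissue, a=s.b, b=s.a, c=s.d, d=s.c)
            for s in strata
        ]
    table = StratifiedTable(gene_id="paradox", strata=tuple(strata))
    _validate_paradox(table, mirror, background_depths)
    return table


def _validate_paradox(table, mirror, background_depths):
    lo, hi = (1.0, math.inf) if mirror else (0.0, 1.0)
    for s in table.strata:
        if not lo < s.odds_ratio < hi:
            raise InfeasibleParadoxError(
                f"stratum {s.tissue} odds ratio {s.odds_ratio:.3f} not in "
                f"({lo}, {hi}); the construction needs opposing sampling "
                "imbalance between strata (cf. balanced depths, which admit "
                "no reversal)"
            )
    a, b, c, d = (int(x.sum()) for x in table.arrays())
    if background_depths is not None:
        bg_n, bg_c = background_depths
        extra_n = max(int(bg_n) - (b + d), 0)
        extra_c = max(int(bg_c) - (a + c), 0)
        d += extra_n
        c += extra_c
    pooled = (a * d) / (b * c)
    ok = pooled < 1 if mirror else pooled > 1
    if not ok:
        raise InfeasibleParadoxError(
            f"pooled odds ratio {pooled:.3f} does not reverse the stratum "
            "direction; increase the sampling imbalance between strata"
        )


#: Table-1-like parameter families known to admit the construction.
def sample_paradox_tables(
    n: int,
    rng: np.random.Generator,
    mirror_half: bool = False,
    stratum_depths: Sequence[tuple[int, int]] | None = None,
    background_depths: tuple[int, int] | None = None,
    max_attempts: int = 200,
) -> list[StratifiedTable]:
    """Draw ``n`` valid paradox constructions with randomized parameters."""
    tables: list[StratifiedTable] = []
    for i in range(n):
        mirror = mirror_half and (i % 2 == 1)
        for _ in range(max_attempts):
            if stratum_depths is None:
                s1 = rng.uniform(0.5, 2.0)
                s2 = rng.uniform(0.5, 2.0)
                depths = [
                    (int(20_000 * s1), int(80_000 * s1)),
                    (int(380_000 * s2), int(620_000 * s2)),
                ]
            else:
                depths = [tuple(int(x) for x in dd) for dd in stratum_depths]
            psi = rng.uniform(0.55, 0.85, size=len(depths))
            r1 = rng.uniform(0.008, 0.02)
            rates = [r1] + [r1 / rng.uniform(100, 400)] * (len(depths) - 1)
            try:
                tables.append(generate_paradox_gene(
                    depths, list(psi), rates, mirror=mirror,
                    background_depths=background_depths,
                ))
                break
            except InfeasibleParadoxError:
                continue
        else:
            raise InfeasibleParadoxError(
                f"no valid construction found in {max_attempts} attempts"
            )
    return tables


# --------------------------------------------------------------------------
# Table 1 canonical fixture
# --------------------------------------------------------------------------


def table1_count_matrix() -> CountMatrix:
    """The canonical contrived two-gene, two-tissue demonstration matrix.

    The focal gene's pooled counts are (normal 300, cancer 600) while every
    stratum's odds ratio is below 1 — the textbook Simpson reversal.
    """
    counts = np.array([
        [[280, 580], [20, 20]],           # focal gene: (normal, cancer) per tissue
        [[20_000, 80_000], [380_000, 620_000]],  # pooled other genes
    ], dtype=np.int64)
    return CountMatrix(
        genes=["GENE_A", "OTHER"],
        tissues=["tissue_I", "tissue_II"],
        counts=counts,
        retained_tissues=["tissue_I", "tissue_II"],
    )


# --------------------------------------------------------------------------
# Library corpus generation (curation + assignment fixtures)
# --------------------------------------------------------------------------


@dataclass
class LibraryCorpus:
    """A synthetic clone-library corpus with planted ground truth."""

    records: list[LibraryRecord]
    psl: pd.DataFrame
    est_library: pd.DataFrame  # est_id -> library_id
    transcript_to_gene: dict[str, str]
    planted_counts: pd.DataFrame  # gene_id, library_id, count (assignable ESTs)
    clean_library_ids: list[str]
    contaminated_library_ids: list[str]
    library_classification: dict[str, tuple[str, str]]  # lib -> (tissue, condition)


_CONTAMINATION_KINDS = ("keyword", "cell_line", "mixed_tissue", "small")
_KEYWORD_PHRASES = {
    "enrichment": "cDNA enrichment protocol applied",
    "subtract": "Subtracted against fetal pool",
    "pcr": "Amplified by long-distance PCR",
    "normalized": "Normalized by reassociation kinetics",
}
#: Decoys per library: ESTs whose only hits fail a filter.
_N_UNASSIGNABLE = 3


def generate_library_corpus(
    n_libraries: int = 60,
    contamination: float = 0.25,
    n_genes: int = 30,
    mean_library_ests: int = 600,
    tissues: Sequence[str] = TOP_TISSUES,
    seed: int = 0,
) -> LibraryCorpus:
    """Generate libraries, planted per-library gene counts and PSL rows.

    Exactly ``floor(contamination * n_libraries)`` libraries carry at least
    one discard trigger (exclusion keyword, cell-line flag, mixed tissue,
    or sub-cutoff size, cycled). Alignment rows realize the planted counts
    at identities/lengths straddling the 95% / 100 nt thresholds: every
    planted EST has one passing hit (some exactly at the boundary), some
    carry an extra sub-threshold decoy hit, and each library adds a few
    ESTs with only failing hits, which must never be counted downstream.
    """
    if not 0.0 <= contamination <= 1.0:
        raise ValidationError("contamination must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"SG{i:03d}" for i in range(n_genes)]
    transcript_to_gene: dict[str, str] = {}
    for g in genes:
        transcript_to_gene[f"NM_{g}_1"] = g
        transcript_to_gene[f"NM_{g}_2"] = g

    n_contaminated = int(math.floor(contamination * n_libraries))
    contaminated_slots = set(
        rng.choice(n_libraries, size=n_contaminated, replace=False).tolist()
    )
    gene_weights = rng.lognormal(0.0, 0.7, size=n_genes)
    gene_weights /= gene_weights.sum()

    records: list[LibraryRecord] = []
    classification: dict[str, tuple[str, str]] = {}
    clean_ids: list[str] = []
    contaminated_ids: list[str] = []
    planted_rows: list[tuple[str, str, int]] = []
    psl_rows: list[dict] = []
    est_lib_rows: list[tuple[str, str]] = []
    contam_cycle = 0

    for i in range(n_libraries):
        lib_id = f"LIB{i:04d}"
        tissue = tissues[i % len(tissues)]
        condition = "cancer" if i % 2 else "normal"
        histology = "adenocarcinoma" if condition == "cancer" else "normal tissue"
        descr = f"{tissue} {histology} cDNA library"
        protocol = "Oligo-dT primed, directionally cloned"
        keywords_field = ""
        is_cell_line = False
        is_mixed = False
        low = max(mean_library_ests // 2, 401)
        n_assignable = int(rng.integers(low, max(mean_library_ests * 2, low + 50)))
        if i in contaminated_slots:
            kind = _CONTAMINATION_KINDS[contam_cycle % len(_CONTAMINATION_KINDS)]
            contam_cycle += 1
            if kind == "keyword":
                kw = list(_KEYWORD_PHRASES)[contam_cycle % len(_KEYWORD_PHRASES)]
                protocol = _KEYWORD_PHRASES[kw]
            elif kind == "cell_line":
                is_cell_line = True
            elif kind == "mixed_tissue":
                is_mixed = True
            else:  # small
                n_assignable = int(rng.integers(20, 300))
            contaminated_ids.append(lib_id)
        else:
            clean_ids.append(lib_id)
        classification[lib_id] = (tissue, condition)

        gene_counts = rng.multinomial(n_assignable, gene_weights)
        est_seq = 0
        for g_i, count in enumerate(gene_counts):
            if count == 0:
                continue
            planted_rows.append((genes[g_i], lib_id, int(count)))
            for _ in range(count):
                est_id = f"{lib_id}.{est_seq:05d}"
                est_seq += 1
                est_lib_rows.append((est_id, lib_id))
                variant = 1 + (est_seq % 2)
                target = f"NM_{genes[g_i]}_{variant}"
                if est_seq % 7 == 0:
                    # exactly at both thresholds: 95.0% identity over 100 nt
                    psl_rows.append(_psl_row(est_id, target, matches=95,
                                             mismatches=5, blocks=(100,)))
                else:
                    psl_rows.append(_psl_row(est_id, target, matches=297,
                                             mismatches=3, blocks=(150, 147)))
                if est_seq % 5 == 0:
                    # inferior decoy hit on another gene; must never win
                    decoy = f"NM_{genes[(g_i + 1) % n_genes]}_1"
                    psl_rows.append(_psl_row(est_id, decoy, matches=284,
                                             mismatches=16, blocks=(300,)))
        for u in range(_N_UNASSIGNABLE):
            est_id = f"{lib_id}.U{u:03d}"
            est_lib_rows.append((est_id, lib_id))
            target = f"NM_{genes[u % n_genes]}_1"
            if u % 2 == 0:
                # identity exactly 94.9%: below the inclusive 95% threshold
                psl_rows.append(_psl_row(est_id, target, matches=949,
                                         mismatches=51, blocks=(500, 500)))
            else:
                # perfect identity but span 99 nt: below the length threshold
                psl_rows.append(_psl_row(est_id, target, matches=99,
                                         mismatches=0, blocks=(99,)))

        records.append(LibraryRecord(
            library_id=lib_id,
            title=f"Synthetic library {i}",
            descr=descr,
            unique_protocol=protocol,
            keywords=keywords_field,
            tissue_label=tissue,
            histology_label=histology,
            est_count=n_assignable + _N_UNASSIGNABLE,
            is_cell_line=is_cell_line,
            is_mixed_tissue=is_mixed,
        ))

    psl = pd.DataFrame(psl_rows)
    planted = pd.DataFrame(planted_rows, columns=["gene_id", "library_id", "count"])
    return LibraryCorpus(
        records=records,
        psl=psl,
        est_library=pd.DataFrame(est_lib_rows, columns=["est_id", "library_id"]),
        transcript_to_gene=transcript_to_gene,
        planted_counts=planted,
        clean_library_ids=clean_ids,
        contaminated_library_ids=contaminated_ids,
        library_classification=classification,
    )


def _psl_row(est_id: str, transcript_id: str, matches: int, mismatches: int,
             blocks: tuple[int, ...]) -> dict:
    span = sum(blocks)
    return {
        "matches": matches, "misMatches": mismatches, "repMatches": 0,
        "nCount": 0, "qNumInsert": 0, "qBaseInsert": 0,
        "tNumInsert": max(len(blocks) - 1, 0), "tBaseInsert": 0,
        "strand": "+", "qName": est_id, "qSize": span + 20, "qStart": 10,
        "qEnd": 10 + span, "tName": transcript_id, "tSize": 2000,
        "tStart": 100, "tEnd": 100 + span, "blockCount": len(blocks),
        "blockSizes": ",".join(str(b) for b in blocks) + ",",
        "qStarts": ",".join(str(10 + sum(blocks[:i])) for i in range(len(blocks))) + ",",
        "tStarts": ",".join(str(100 + sum(blocks[:i]) + i) for i in range(len(blocks))) + ",",
    }


# --------------------------------------------------------------------------
# Fixture writers (the `simulate` CLI subcommand)
# --------------------------------------------------------------------------


def write_corpus(corpus: LibraryCorpus, outdir: str | Path) -> dict[str, Path]:
    """Write all corpus fixtures in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "libraries": outdir / "libraries.tsv",
        "psl": outdir / "alignments.psl",
        "est_library": outdir / "est_library.tsv",
        "gene_map": outdir / "gene_map.tsv",
        "planted_counts": outdir / "planted_counts.tsv",
    }
    lib_frame = pd.DataFrame([{
        "library_id": r.library_id, "descr": r.descr,
        "unique_protocol": r.unique_protocol, "keywords": r.keywords,
        "tissue_label": r.tissue_label, "histology_label": r.histology_label,
        "est_count": r.est_count,
        "is_cell_line": str(r.is_cell_line).lower(),
        "is_mixed_tissue": str(r.is_mixed_tissue).lower(),
    } for r in corpus.records])
    lib_frame.to_csv(paths["libraries"], sep="\t", index=False)
    corpus.psl.to_csv(paths["psl"], sep="\t", index=False, header=False)
    corpus.est_library.to_csv(paths["est_library"], sep="\t", index=False)
    pd.Series(corpus.transcript_to_gene).rename_axis("transcript_id").rename(
        "gene_id"
    ).to_csv(paths["gene_map"], sep="\t", header=False)
    corpus.planted_counts.to_csv(paths["planted_counts"], sep="\t", index=False)
    return paths
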