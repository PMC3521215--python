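"""Stratified 2x2xk association testing for digital expression counts.

For each focal gene, all remaining genes are pooled into an "other genes"
row, giving one 2x2 table (gene/other x cancer/normal) per retained tissue.
Tissue is a confounder of EST sampling — depths differ wildly between
tissues and conditions — so association is tested conditionally on the
tissue strata.

Implemented here, per gene:

* the Cochran-Mantel-Haenszel (CMH) chi-square statistic

      chi2 = ( |sum_i a_i - sum_i E_i| - 1/2 )^2 / sum_i V_i

  with ``E_i = r1_i c1_i / n_i`` and hypergeometric variance
  ``V_i = r1_i r2_i c1_i c2_i / (n_i^2 (n_i - 1))``; p from chi2 with 1 df
  (the 1/2 continuity correction is on by default and optional);

* the Mantel-Haenszel common odds ratio

      theta_hat = sum_i (a_i d_i / n_i) / sum_i (b_i c_i / n_i)

  with its confidence interval from the Robins-Breslow-Greenland (RBG)
  variance of log theta_hat (a Woolf-weight variance is available as a
  sensitivity alternative);

* the naive pooled 2x2 analysis (sum the strata, cross-product odds ratio,
  Yates-corrected chi-square), kept alongside to diagnose Simpson's
  paradox: "reversed" when pooled and stratified odds ratios sit on
  opposite sides of 1, "attenuated" when they agree in direction but
  disagree in significance;

* Woolf's test for homogeneity of the per-stratum odds ratios, with the
  Haldane-Anscombe +0.5 adjustment applied within any stratum containing a
  zero cell;

* the selection rule: CMH p < alpha and CI lower bound >= a cutoff
  (defaults 0.05 and 1.65).

Cells follow the convention a = focal gene in cancer, b = focal gene in
normal, c = other genes in cancer, d = other genes in normal.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    DEFAULT_ALPHA,
    DEFAULT_CI_LEVEL,
    DEFAULT_CI_LOWER_MIN,
)
from .count_engine import CountMatrix
from .errors import UndefinedResultError, ValidationError

SIMPSON_FLAGS = ("concordant", "attenuated", "reversed", "undefined")

# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StratumTable:
    """One tissue's 2x2 slice: focal gene vs pooled others, cancer vs normal."""

    tissue: str
    a: int  # focal gene, cancer
    b: int  # focal gene, normal
    c: int  # other genes, cancer
    d: int  # other genes, normal

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError(f"stratum {self.tissue}: negative cell")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def odds_ratio(self) -> float:
        """Cross-product odds ratio of this stratum (nan/inf on zero cells)."""
        num, den = self.a * self.d, self.b * self.c
        if den == 0:
            return math.nan if num == 0 else math.inf
        return num / den

    @property
    def informative(self) -> bool:
        """True when all four margins are positive (contributes to CMH)."""
        return (
            self.a + self.b > 0 and self.c + self.d > 0
            and self.a + self.c > 0 and self.b + self.d > 0
        )


@dataclass(frozen=True)
class StratifiedTable:
    """Per-gene 2x2xk table over the retained tissues (alphabetical order)."""

    gene_id: str
    strata: tuple[StratumTable, ...]

    @property
    def k(self) -> int:
        return len(self.strata)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        a = np.array([s.a for s in self.strata], dtype=float)
        b = np.array([s.b for s in self.strata], dtype=float)
        c = np.array([s.c for s in self.strata], dtype=float)
        d = np.array([s.d for s in self.strata], dtype=float)
        return a, b, c, d

    @property
    def n_informative(self) -> int:
        return sum(s.informative for s in self.strata)


@dataclass
class GeneTestResult:
    """All per-gene statistics; undefined quantities are NaN."""

    gene_id: str
    a_total: int
    b_total: int
    cmh_statistic: float
    cmh_p: float
    or_mh: float
    ci_level: float
    ci_lower: float
    ci_upper: float
    pooled_or: float
    pooled_chi2_p: float
    woolf_statistic: float
    woolf_df: int
    woolf_p: float
    simpson_flag: str
    n_informative_strata: int
    selected: bool


class PooledResult:
    """Pooled 2x2 summary: table (a, b, c, d), odds ratio, chi2 p-value."""

    __slots__ = ("table", "odds_ratio", "p_value")

    def __init__(self, table, odds_ratio, p_value):
        self.table = table
        self.odds_ratio = odds_ratio
        self.p_value = p_value

    def __iter__(self):
        return iter((self.table, self.odds_ratio, self.p_value))


# --------------------------------------------------------------------------
# Table construction
# --------------------------------------------------------------------------


def build_gene_table(matrix: CountMatrix, gene_id: str) -> StratifiedTable:
    """Build the gene's 2x2xk table over retained tissues.

    a, b are the gene's cancer/normal counts per tissue; c, d are the
    stratum column totals minus the gene's cells (all other genes pooled).
    """
    g = matrix.gene_index(gene_id)
    tissues = matrix.analysis_tissues()
    if not tissues:
        raise ValidationError("no retained tissues")
    totals = matrix.stratum_totals()
    strata = []
    for tissue in sorted(tissues):
        t = matrix.tissue_index(tissue)
        b, a = int(matrix.counts[g, t, 0]), int(matrix.counts[g, t, 1])
        d, c = int(totals[t, 0]) - b, int(totals[t, 1]) - a
        strata.append(StratumTable(tissue=tissue, a=a, b=b, c=c, d=d))
    return StratifiedTable(gene_id=gene_id, strata=tuple(strata))


# --------------------------------------------------------------------------
# Statistics
# --------------------------------------------------------------------------


def _cmh_components(table: StratifiedTable):
    a, b, c, d = table.arrays()
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    ok = (r1 > 0) & (r2 > 0) & (c1 > 0) & (c2 > 0) & (n > 1)
    E = np.where(ok, r1 * c1 / np.where(n > 0, n, 1), 0.0)
    V = np.where(ok, r1 * r2 * c1 * c2 / (n**2 * np.maximum(n - 1, 1)), 0.0)
    return a, E, V, ok


def cmh_test(table: StratifiedTable, continuity_correction: bool = True) -> tuple[float, float]:
    """CMH chi-square statistic and two-sided p-value (chi2, 1 df).

    Strata with a zero row or column margin contribute nothing; raises
    :class:`UndefinedResultError` when every stratum is degenerate.
    """
    a, E, V, ok = _cmh_components(table)
    sum_v = float(V.sum())
    if sum_v <= 0 or not ok.any():
        raise UndefinedResultError(
            f"gene {table.gene_id}: all strata degenerate, CMH undefined"
        )
    dev = abs(float(a[ok].sum()) - float(E.sum()))
    if continuity_correction:
        dev = max(dev - 0.5, 0.0)
    statistic = dev**2 / sum_v
    return statistic, float(stats.chi2.sf(statistic, 1))


def mh_common_or(table: StratifiedTable) -> float:
    """Mantel-Haenszel common odds ratio (weighted average across strata)."""
    a, b, c, d = table.arrays()
    n = a + b + c + d
    with np.errstate(invalid="ignore"):
        R = np.where(n > 0, a * d / np.where(n > 0, n, 1), 0.0)
        S = np.where(n > 0, b * c / np.where(n > 0, n, 1), 0.0)
    sum_r, sum_s = float(R.sum()), float(S.sum())
    if sum_s == 0:
        raise UndefinedResultError(
            f"gene {table.gene_id}: zero MH denominator, common OR undefined"
        )
    return sum_r / sum_s


def mh_or_ci(
    table: StratifiedTable,
    level: float = DEFAULT_CI_LEVEL,
    method: str = "rbg",
) -> tuple[float, float]:
    """Confidence interval for the MH common odds ratio.

    ``method='rbg'`` (default) uses the Robins-Breslow-Greenland variance of
    log theta_hat; ``method='woolf'`` uses the inverse-variance (Woolf
    weight) alternative on Haldane-adjusted strata.
    """
    theta = mh_common_or(table)
    if theta <= 0 or not math.isfinite(theta):
        raise UndefinedResultError(
            f"gene {table.gene_id}: CI undefined for MH OR {theta}"
        )
    if method == "rbg":
        se = _rbg_se(table)
    elif method == "woolf":
        w, _ = _woolf_weights(table)
        if w.sum() <= 0:
            raise UndefinedResultError(f"gene {table.gene_id}: degenerate variance")
        se = math.sqrt(1.0 / float(w.sum()))
    else:
        raise ValidationError(f"unknown CI method {method!r}")
    if not math.isfinite(se) or se <= 0:
        raise UndefinedResultError(f"gene {table.gene_id}: degenerate variance")
    z = stats.norm.ppf(0.5 + level / 2)
    log_theta = math.log(theta)
    return math.exp(log_theta - z * se), math.exp(log_theta + z * se)


def _rbg_se(table: StratifiedTable) -> float:
    a, b, c, d = table.arrays()
    n = a + b + c + d
    nz = n > 0
    a, b, c, d, n = a[nz], b[nz], c[nz], d[nz], n[nz]
    R, S = a * d / n, b * c / n
    P, Q = (a + d) / n, (b + c) / n
    sum_r, sum_s = R.sum(), S.sum()
    if sum_r == 0 or sum_s == 0:
        return math.nan
    var = (
        float((P * R).sum()) / (2 * sum_r**2)
        + float((P * S + Q * R).sum()) / (2 * sum_r * sum_s)
        + float((Q * S).sum()) / (2 * sum_s**2)
    )
    return math.sqrt(var)


def pooled_analysis(table: StratifiedTable) -> PooledResult:
    """Naive pooled 2x2 analysis: sum strata, cross-product OR, Yates chi2.

    This is the analysis the stratified test is guarding against; its
    disagreement with the CMH result is the Simpson's-paradox diagnostic.
    """
    if not table.strata:
        raise ValidationError("empty stratified table")
    a, b, c, d = (int(x.sum()) for x in table.arrays())
    num, den = a * d, b * c
    pooled_or = math.nan if den == 0 else num / den
    try:
        _, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=True)
        p = float(p)
    except ValueError:
        p = math.nan
    return PooledResult((a, b, c, d), pooled_or, p)


def _woolf_weights(table: StratifiedTable):
    """Woolf weights and per-stratum log odds ratios.

    Only informative strata (all four margins positive) enter; any such
    stratum containing a zero cell gets +0.5 added to all four of its cells
    (Haldane-Anscombe), applied within that stratum only.
    """
    cells = []
    for s in table.strata:
        if not s.informative:
            continue
        a, b, c, d = s.a, s.b, s.c, s.d
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        cells.append((a, b, c, d))
    if not cells:
        return np.empty(0), np.empty(0)
    arr = np.array(cells, dtype=float)
    a, b, c, d = arr.T
    w = 1.0 / (1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(a * d / (b * c))
    return w, log_or


def woolf_test(table: StratifiedTable) -> tuple[float, int, float]:
    """Woolf's chi-square test of odds-ratio homogeneity across strata.

    statistic = sum_i w_i (ln OR_i - ln OR_bar)^2 with OR_bar the
    weight-averaged log odds ratio; df = informative strata - 1.
    """
    w, log_or = _woolf_weights(table)
    if len(w) < 2:
        raise UndefinedResultError(
            f"gene {table.gene_id}: < 2 informative strata, homogeneity undefined"
        )
    mean_log = float((w * log_or).sum() / w.sum())
    statistic = float((w * (log_or - mean_log) ** 2).sum())
    df = len(w) - 1
    return statistic, df, float(stats.chi2.sf(statistic, df))


def classify_simpson(
    pooled_or: float,
    pooled_p: float,
    or_mh: float,
    cmh_p: float,
    alpha: float = DEFAULT_ALPHA,
) -> str:
    """Compare the pooled and stratified views of one gene.

    reversed   — odds ratios on opposite sides of 1 (the paradox proper)
    attenuated — same direction but the significance verdicts disagree
    concordant — otherwise
    undefined  — either odds ratio undefined
    """
    if not (math.isfinite(pooled_or) and math.isfinite(or_mh)) or min(pooled_or, or_mh) <= 0:
        return "undefined"
    s_pooled = pooled_or - 1.0
    s_strat = or_mh - 1.0
    if s_pooled * s_strat < 0:
        return "reversed"
    pooled_sig = math.isfinite(pooled_p) and pooled_p < alpha
    cmh_sig = math.isfinite(cmh_p) and cmh_p < alpha
    if pooled_sig != cmh_sig:
        return "attenuated"
    return "concordant"


def simpson_flag(result: GeneTestResult, alpha: float = DEFAULT_ALPHA) -> str:
    return classify_simpson(
        result.pooled_or, result.pooled_chi2_p, result.or_mh, result.cmh_p, alpha
    )


# --------------------------------------------------------------------------
# Per-gene driver and the whole-matrix sweep
# --------------------------------------------------------------------------


def gene_test(
    table: StratifiedTable,
    alpha: float = DEFAULT_ALPHA,
    ci_lower_min: float = DEFAULT_CI_LOWER_MIN,
    ci_level: float = DEFAULT_CI_LEVEL,
    continuity_correction: bool = True,
    ci_method: str = "rbg",
) -> GeneTestResult:
    """Run every statistic on one gene's table; undefined results become NaN."""
    nan = math.nan
    try:
        cmh_stat, cmh_p = cmh_test(table, continuity_correction)
    except UndefinedResultError:
        cmh_stat = cmh_p = nan
    try:
        or_mh = mh_common_or(table)
    except UndefinedResultError:
        or_mh = nan
    try:
        ci_lower, ci_upper = mh_or_ci(table, ci_level, ci_method)
    except UndefinedResultError:
        ci_lower = ci_upper = nan
    try:
        _, pooled_or, pooled_p = pooled_analysis(table)
    except ValidationError:
        pooled_or = pooled_p = nan
    try:
        w_stat, w_df, w_p = woolf_test(table)
    except UndefinedResultError:
        w_stat, w_df, w_p = nan, 0, nan
    flag = classify_simpson(pooled_or, pooled_p, or_mh, cmh_p, alpha)
    a, b, _, _ = table.arrays()
    selected = bool(
        math.isfinite(cmh_p) and cmh_p < alpha
        and math.isfinite(ci_lower) and ci_lower >= ci_lower_min
    )
    return GeneTestResult(
        gene_id=table.gene_id,
        a_total=int(a.sum()),
        b_total=int(b.sum()),
        cmh_statistic=cmh_stat,
        cmh_p=cmh_p,
        or_mh=or_mh,
        ci_level=ci_level,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        pooled_or=pooled_or,
        pooled_chi2_p=pooled_p,
        woolf_statistic=w_stat,
        woolf_df=w_df,
        woolf_p=w_p,
        simpson_flag=flag,
        n_informative_strata=table.n_informative,
        selected=selected,
    )


RESULT_COLUMNS = (
    "gene", "a_total", "b_total", "cmh_stat", "cmh_p", "or_mh", "ci_lower",
    "ci_upper", "pooled_or", "pooled_chi2_p", "woolf_stat", "woolf_df",
    "woolf_p", "simpson_flag", "selected",
)


def run_all_genes(
    matrix: CountMatrix,
    alpha: float = DEFAULT_ALPHA,
    ci_lower_min: float = DEFAULT_CI_LOWER_MIN,
    ci_level: float = DEFAULT_CI_LEVEL,
    continuity_correction: bool = True,
    ci_method: str = "rbg",
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Test every gene of the matrix against the pooled rest.

    Returns one row per gene in the matrix's (deterministic) gene order;
    per-gene undefined statistics appear as NaN, never abort the sweep.
    ``bh_adjust`` adds a Benjamini-Hochberg column ``cmh_p_bh`` for
    reporting only — selection always uses the raw p-value rule.
    """
    if len(matrix.genes) < 2:
        raise ValidationError("need >= 2 genes (others are pooled against each)")
    rows = []
    for gene in matrix.genes:
        table = build_gene_table(matrix, gene)
        r = gene_test(
            table,
            alpha=alpha,
            ci_lower_min=ci_lower_min,
            ci_level=ci_level,
            continuity_correction=continuity_correction,
            ci_method=ci_method,
        )
        rows.append((
            r.gene_id, r.a_total, r.b_total, r.cmh_statistic, r.cmh_p,
            r.or_mh, r.ci_lower, r.ci_upper, r.pooled_or, r.pooled_chi2_p,
            r.woolf_statistic, r.woolf_df, r.woolf_p, r.simpson_flag,
            r.selected,
        ))
    df = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    if bh_adjust:
        p = df["cmh_p"].to_numpy(dtype=float)
        adj = np.full_like(p, np.nan)
        finite = np.isfinite(p)
        if finite.any():
            adj[finite] = stats.false_discovery_control(p[finite], method="bh")
        df["cmh_p_bh"] = adj
    return df


def select_candidates(
    results: pd.DataFrame,
    p_threshold: float = DEFAULT_ALPHA,
    ci_lower_min: float = DEFAULT_CI_LOWER_MIN,
) -> pd.DataFrame:
    """Genes with CMH p < threshold and CI lower bound >= cutoff.

    Both criteria operate on defined values only: a gene with an undefined
    CI is never selected, whatever its point estimate.
    """
    p = results["cmh_p"]
    lo = results["ci_lower"]
    mask = p.notna() & (p < p_threshold) & lo.notna() & (lo >= ci_lower_min)
    return results[mask]


def write_results_tsv(results: pd.DataFrame, path: str | Path) -> None:
    """Results TSV with p-values in scientific notation below 1e-4."""
    out = results.copy()
    for col in ("cmh_p", "pooled_chi2_p", "woolf_p", "cmh_p_bh"):
        if col in out.columns:
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6g}")
    for col in ("cmh_stat", "or_mh", "ci_lower", "ci_upper", "pooled_or", "woolf_stat"):
        if col in out.columns:
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False)
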