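# Methods

## Model and procedure

The pipeline treats EST counts as a digital sample of the transcriptome:
within one (tissue, condition) stratum, the vector of per-gene counts is
modeled as multinomial over genes with the stratum's total depth fixed.
For a focal gene, the stratum reduces to a 2×2 table (focal vs pooled
other genes × cancer vs normal), and the per-gene analysis is a 2×2×k
stratified contingency problem over the k retained tissues, one 2×2 slice
per tissue containing both conditions. This follows the demonstration
table's arithmetic; stratifying by (tissue × condition) would leave no
condition contrast within a stratum, so k is the number of retained
tissues.

Assumptions worth stating:

- The "other genes" row is dominated by genes that are not differentially
  expressed (or whose differential expression cancels), so the cancer vs
  normal imbalance of that row measures sampling bias, not biology.
- The CMH test is used for hypothesis testing even when per-tissue odds
  ratios are heterogeneous; the MH common odds ratio is then read as a
  depth-weighted summary ("averaged up" across tissues), not as an
  estimate of a common parameter. Woolf's test is reported per gene so
  heterogeneous genes can be recognized.
- Library pooling (libraries of the same tissue merged) and variant
  pooling (transcripts of the same gene merged) are deliberate: the data
  are too shallow to resolve patients or isoforms.

## Statistics implemented

- **CMH**: χ² = (|Σaᵢ − ΣEᵢ| − ½)²/ΣVᵢ, Eᵢ = r1ᵢc1ᵢ/nᵢ,
  Vᵢ = r1ᵢr2ᵢc1ᵢc2ᵢ/(nᵢ²(nᵢ−1)), p from χ²₁, two-sided. The ½ continuity
  correction is on by default and can be disabled; strata with a zero row
  or column margin contribute nothing, and a table with no informative
  stratum is reported undefined (NaN in the sweep), never 0.
- **MH common OR**: θ̂ = Σ(aᵢdᵢ/nᵢ)/Σ(bᵢcᵢ/nᵢ) on raw counts (the sums
  absorb zeros naturally). θ̂ = 0 (focal gene absent from cancer) is a
  defined estimate with an undefined CI; a zero denominator is undefined.
- **CI**: exp(ln θ̂ ∓ z·SE) with SE from the Robins-Breslow-Greenland
  variance — the field-standard choice, which at k=1 reduces exactly to
  the classical log-OR variance 1/a+1/b+1/c+1/d. A Woolf (inverse-variance)
  SE is available behind `ci_method="woolf"` as a sensitivity check, since
  the CI construction used for the published intervals is not documented.
- **Pooled view**: strata summed, cross-product OR, Yates-corrected 2×2
  χ² (scipy). Note the k=1 CMH and the Yates χ² differ by a factor
  (n−1)/n: the CMH uses the hypergeometric variance. The closed-form
  check in the tests uses the Mantel-Haenszel form.
- **Woolf homogeneity**: wᵢ = (1/aᵢ+1/bᵢ+1/cᵢ+1/dᵢ)⁻¹,
  X² = Σwᵢ(ln ORᵢ − ln ŌR)², ŌR the w-weighted geometric mean, df =
  informative strata − 1. Informative means all four margins positive;
  any informative stratum containing a zero cell gets the
  Haldane-Anscombe +0.5 added to all four of its cells, within that
  stratum only. CMH and the MH OR always use raw counts.
- **Simpson flag**: `reversed` when (pooled OR − 1) and (θ̂ − 1) have
  opposite signs; `attenuated` (a refinement beyond the classical
  reversal) when they agree in direction but the pooled χ² and CMH
  significance verdicts at α disagree; `concordant` otherwise;
  `undefined` when either OR is undefined. Undefined p-values compare as
  "not significant" for the attenuation check.
- **Selection**: CMH p < α (default 0.05) AND CI lower bound ≥ 1.65.
  Raw p-values, matching the original protocol; a Benjamini-Hochberg
  column is available for reporting but never feeds selection.

## Thresholds and defaults

| parameter | default | meaning |
|---|---|---|
| exclusion keywords | enrichment, subtract, pcr, normalized | abundance-distorting protocols; case-insensitive substring over DESCR/UNIQUE_PROTOCOL/KEYWORDS |
| min library ESTs | 400 | keep libraries with strictly more than 400 ESTs |
| min identity | 95.0% | inclusive; identity = 100·matches/aligned span (blocks summed); matches/(matches+mismatches) variant available |
| min aligned span | 100 nt | applies to the aligned span, not query length |
| min tissue depth | 20,000 | a tissue enters the strata only strictly above this; shallower tissues are stored but contribute nothing |
| α | 0.05 | CMH significance |
| CI level / lower bound | 0.95 / 1.65 | selection on the interval, not the point estimate |
| microarray DE | p < 0.05, log₂FC > 1.0 | strict; signed (up in cancer), absolute-value mode behind a flag |

Word-boundary keyword matching is off (the protocol names keywords, not a
matching rule). The manual-curation pass is modeled as an override table
(library_id → forced decision) applied after rule evaluation. ESTs whose
best hits reach transcripts of different genes are resolved by the same
best-hit rule (highest identity, then first encountered).

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the method was built
for: ~1.64 million assigned ESTs, 48 tissues with brain at 26% and the
published top-8 shares, a ~3:1 normal:cancer depth ratio with per-tissue
variation (heart sampled only in normal, some tissues below the depth
cutoff), log-normal gene abundances, and per-stratum multinomial counts.
A gene's cancer proportion is tilted on the odds scale
(p' = θp/(1−p+θp)) so its true conditional odds ratio is exactly θ per
stratum up to renormalization over the other genes (negligible for rare
genes). Paradox genes are constructed deterministically in the
demonstration-table pattern — concentrated in a cancer-oversampled
stratum, every stratum OR < 1, pooled OR > 1 — and validated on the
integer table; balanced sampling between strata is correctly reported
infeasible. Library corpora plant exact per-library gene counts realized
as PSL rows straddling the 95%/100 nt thresholds, plus decoy hits and
unassignable ESTs.

Not emulated: real sequence content (alignments are summary-level),
patient-level library heterogeneity, isoform structure, and annotation or
microarray noise. Passing tests therefore demonstrate the machinery and
its calibration under the sampling model, not robustness to biological
artifacts of real repositories.

## Calibration and problem sizes

The type-I error of the sweep is checked on 10,000 exchangeable null
genes (flat abundances, 8 deep tissues, 1.6 million ESTs, fixed 3:1
balance) with the continuity correction off: the correction is
deliberately conservative, so calibration is meaningful only for the
uncorrected statistic; both modes are exercised functionally elsewhere.
Interval coverage is checked with 500 replicates at each θ ∈ {0.5, 1, 2,
4} on 8 strata of depth 40,000 (focal rate 0.005); the ±2% acceptance
band is approximately ±2 binomial SD, so occasional excursions at other
seeds are expected Monte-Carlo behavior. End-to-end conservation uses a
100-library corpus at 30% contamination. These sizes keep the whole suite
in the tens of seconds while leaving estimator noise well below the
tolerances.

## Known limitations and open choices

- The published 460-library curation, the 20,000-hit tissue set and the
  723→235→96 candidate cascade depend on 2009 snapshots of dbEST, GEO and
  the annotation databases and are not reproducible from code alone; the
  pipeline reproduces the rules, and the tests validate them on planted
  ground truth instead.
- Identity is computed from PSL summary columns; BLAT's own percent
  identity (with gap penalties) differs slightly. Both available
  definitions are documented and configurable.
- The microarray probe→gene summarization is upstream of this package:
  DE tables are consumed at gene level, whatever produced them.
- Exact-conditional CMH and the Breslow-Day test are out of scope; Woolf
  is the homogeneity test reported.
- `attenuated` is this package's refinement of the Simpson diagnostic;
  only `reversed` corresponds to the classical paradox.
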