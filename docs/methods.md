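# Methods

## Problem setting

A transcription factor (p63) is profiled by ChIP-seq in two conditions —
wild type (WT) and knockout (KO) of a modulator (iASPP) — together with
replicated RNA-seq. The questions the pipeline answers: which peaks gain
or lose binding after the knockout; which partner-TF sequence motifs best
explain the binding shifts; whether the shift concentrates at peaks with
weak motifs for the profiled factor itself; and whether genes near shifted
peaks are preferentially up-regulated. This package implements those four
stages and a synthetic-data generator that plants known answers, so the
whole chain can be validated by recovery.

## Differential binding (MA stage)

Per peak with counts (x_WT, x_KO) and pseudocount c = 1:

    M_raw = log2(x_KO + c) − log2(x_WT + c)
    A     = ½ (log2(x_KO + c) + log2(x_WT + c))

**Normalization.** A robust line M = a + b·A is fitted on "common" peaks —
by default those with |M_raw| below its median, a stand-in for peaks
occupied in both conditions, which the count table alone cannot label —
and subtracted from every peak's M_raw. The fit is Theil–Sen (median of
pairwise slopes; intercept = median residual, scipy's `joint` method),
chosen because it is deterministic, tuning-free, and resistant to the
minority of genuinely changed peaks leaking into the common set; the
`joint` intercept makes refitting after normalization the exact identity.

**Significance.** The symmetric count-comparison statistic with terms

    P(y | x) = (x + y)! / (x! · y! · 2^(x+y+1))

i.e. the posterior predictive of a Poisson rate under a flat prior;
P(y|x) is the negative-binomial pmf NB(r = x+1, p = ½), so tails are
computed exactly via `scipy.stats.nbinom`. The reported p-value is the
one-sided tail P(Y ≥ max(x, y) | min(x, y)), doubled and capped at 1.
Using max/min rather than conditioning on one fixed margin makes the
statistic exactly symmetric, so swapping condition labels swaps the
enriched_KO and enriched_WT sets exactly. Peaks with p < 5×10⁻³ are
classified by the sign of normalized M; the three classes partition the
peak set.

The statistic models Poisson sampling within conditions. Its null
calibration is therefore checked at generator dispersion 0; with
overdispersed counts it is anti-conservative (a property shared by the
published method family it stands in for) — users should treat the 5×10⁻³
cut as a ranking device, not a strict error rate, when dispersion is
material.

**Exclusion filter.** Peaks overlapping any interval of a supplied
blacklist BED by ≥ 1 bp (0-based half-open) are dropped before analysis.

## Motif scanning

**PWM.** From counts n_bj with column sums N_j, background q_b and
pseudocount s = 0.1 distributed by background:

    w_bj = log2( (n_bj + s·q_b) / (N_j + s) / q_b )

Zero cells with zero pseudocount would give −∞ and are rejected. The
background is order-0, estimated from the scanned sequence set by default
(configurable to uniform); order-0 keeps the p-value DP exact.

**Best hit.** The maximum windowed score over all offsets, both strands
(reverse-complement scanning is the default; double-stranded binding is
symmetric). Ties break by smallest offset, then '+' strand. Windows
containing N are skipped, not imputed.

**Score p-value.** P(window score ≥ s) under the background is computed by
dynamic programming: column scores are discretized to g = 10⁻³ bits and
the pmf of their sum is built by one convolution per column. The survival
lookup subtracts a guard of ⌈w/2⌉+1 bins, so rounding can only make the
p-value minutely conservative (by the probability mass within ~w·g of the
threshold), never anti-conservative; g = 10⁻³ keeps the worst-case error
far below the 10⁻³ FDR decision boundary. For width ≤ 5 the DP is checked
against exhaustive 4^w enumeration.

**Per-peak p-value and presence.** The best hit over n scanned windows
gets the Šidák length correction p_peak = 1 − (1 − p_window)^n. This
correction is what makes BH across peaks meaningful: the raw single-window
p-value of a best-of-~1200-windows statistic is so anti-conservative that
a 10⁻³ FDR target cannot be met (on pure-null data the step-up can reject
every peak once the window count exceeds the reciprocal threshold).
Overlapping windows are positively dependent, so the correction is mildly
conservative. Presence per motif is then BH across peaks at FDR 10⁻³.

## Association statistics

**Motif ranking.** For each motif, Spearman's ρ (Pearson on mid-ranks,
scipy) between per-peak best scores and normalized M over all peaks;
descending-ρ ranking, ties broken by motif id. Negating M negates every ρ
exactly, reversing the ranking.

**Quintile stratification.** Quintile boundaries are the 20/40/60/80th
percentiles of the p63 best-score distribution over the full analyzed peak
set (KO- and WT-enriched peaks pooled for boundary-setting; fractions then
reported per class — the pooling choice is ours and stated). Scores tied
with a boundary fall in the lower stratum. Per stratum we report the
AP1-presence fraction among enriched_KO and enriched_WT peaks separately;
an empty class in a stratum reports 0.0.

**Enrichment.** For a gene subcategory S within reference set R (genes
passing the expression filter), the 2×2 table is (in S vs R∖S) ×
(up_KO vs not). Comparing S against the full set R would be degenerate
(S ⊂ R), so the complement is used — the standard contingency
construction. OR = ad/bc with 0.5 added to every cell only when some cell
is zero; χ² is Pearson's without continuity correction (1 df); a
degenerate margin reports χ² = 0, p = 1. No multiple-testing correction is
applied across subcategories (raw ORs and p-values are reported). The
up_KO-vs-rest dichotomy is the default; the direction is configurable.

## Peak annotation

Anchor = peak midpoint (integer floor) — a symmetric, deterministic choice
where summit information does not exist. Nearest TSS on the same
chromosome wins; equidistant ties go to the smaller gene id; peaks on
geneless chromosomes are reported unassigned and excluded downstream.
Distance is signed positive-downstream relative to the gene's strand;
categories use |d|, promoter |d| ≤ 2000, enhancer 2000 < |d| ≤ 20000
(both boundaries inclusive on the proximal side), other beyond. A gene is
"bound" if ≥ 1 assigned peak lies within 20 kb.

## Differential expression (stand-in)

A deliberately lightweight NB fit, not a clone of the reference tool the
real study used; the acceptance surface here is synthetic-truth recovery,
not bit-compatibility.

- **Size factors:** median-of-ratios against the per-gene geometric mean
  over all-positive genes, rescaled to geometric mean 1 (a stated
  convention; sample-scaling then moves results only through the scaled
  sample's factor, and log2FC only through the O(c/μ) lfc pseudocount).
- **Dispersion:** per-gene method-of-moments α = (s² − μ)/μ² pooled within
  conditions, shrunk 75% toward a trend fitted by regressing α on 1/μ,
  floored at 10⁻⁸. The heavy trend weight stabilizes 2–4-replicate
  designs deterministically.
- **Test:** Wald z on log2FC = log2((μ_KO + ½)/(μ_WT + ½)) with
  delta-method SE from the NB variance, normal reference. With the
  trend-shrunk dispersions the normal reference is near-nominal (raw
  p < 0.05 rate ≈ 0.054 on null 3+3 NB data); a t reference with the
  naive residual df overshoots into strong conservatism and destroys
  power. The far sub-10⁻³ tail remains somewhat anti-conservative for
  low-mean genes — a known limitation of moment fits.
- **Classes:** BH across tested genes; up_KO / up_WT at adjusted p < 0.05
  by fold-change sign; genes failing the low-count filter (total < 10)
  are untested and classed unchanged.
- **Batch:** optional labels are handled by per-batch centering of log
  counts (grand mean restored) before testing — a documented
  simplification, not a claim about the original design matrix.

## Synthetic-data generator

Defaults are the study conditions used throughout the tests and the
acceptance script:

| parameter | default | meaning |
|---|---|---|
| n_peaks / peak_length | 1000 / 600 bp | peak set size and width |
| gc_fraction | 0.42 | order-0 background, mouse-like |
| p63_prob | 0.40 | peaks with a planted p63-like motif |
| ap1 plant prob | 0.45 / 0.075 (no p63 / p63) | ≈ 30% overall, anti-correlated with p63 so the effect sits at weak-p63 peaks |
| mean_count / dispersion | 50 / 0.05 | NB per-condition counts (α = 0 → Poisson) |
| log2_binding_effect | 1.0 | multiplies the KO mean of AP1 peaks |
| peak_spacing | 50 kb | sparse enough that effect peaks reach only a minority of genes |
| n_genes | 1000 + 25-gene cluster | ~1 gene / 50 kb; cluster on its own chromosome |
| replicates / mean / dispersion | 3+3 / 100 (lognormal σ=1) / 0.05 | gene counts |
| log2 expression effects | 1.0 near effect peaks; 2.0 in cluster | KO up |

Motifs: an idealized sharp AP1-like 14-mer (0.95 on the consensus letter
per column — wide and sharp enough that a planted sample is individually
detectable at presence FDR 10⁻³ inside a 600 bp peak) and a softer
p63-like 20-mer (two RRRCATGYYY half-sites, 0.70 per column — giving a
broad score distribution for quintile stratification). Plants are sampled
column-wise from the motif probabilities, reverse-complemented on '−', at
recorded non-overlapping positions. Decoys for ranking tests are
column-order shuffles of the AP1 matrix (information content preserved,
specificity destroyed). WT is the reference condition: the binding effect
multiplies only the KO mean, so positive M means enriched in KO.

What the generator does **not** emulate: read-level artifacts (alignment,
duplicates, fragment-length effects), higher-order sequence composition,
chromatin-state or CNV structure, correlated dispersion across peaks, and
motif co-occurrence beyond the planted AP1/p63 anti-correlation. Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under its stated model, not robustness to every artifact of
real data.

## Numerical and design notes

- All coordinates are 0-based half-open internally (BED convention).
- Determinism: every stochastic step takes an explicit seed; pipeline
  sub-seeds derive from one root via `SeedSequence.spawn`; reruns are
  byte-identical.
- Degenerate inputs fail loudly: < 2 common peaks or constant A for the
  normalization fit, constant input to Spearman (NaN with a warning),
  empty subcategories, < 5 peaks for quintiles, < 2 replicates per
  condition.
- Problem sizes in the test-suite simulations (≥ 2000–4000 units for
  calibration checks, 20 seeds for recovery rates, 10 in the acceptance
  script) were chosen to keep Monte-Carlo error well inside the asserted
  bands at desk scale.

## Known limitations

- The common-peak definition (|M| below median) and the count model are
  stand-ins for the published normalization tool's internals, which are
  not specified by the analysis description this package follows.
- Binding significance is anti-conservative under overdispersion (above).
- The DE stage's extreme tail is anti-conservative for low-mean genes;
  fold-change shrinkage (as the real study's 'ashr' step provides) is out
  of scope.
- One gene per peak (nearest TSS only); no isoform-level annotation.
- Quintile pooling and the enrichment dichotomy involve stated choices
  where the original description is ambiguous; both are configurable.
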