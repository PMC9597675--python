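# Methods

`utrld` re-implements, as a tested pipeline, a case-control analysis of the
HLA-G 3' untranslated region in type-1 autoimmune hepatitis: haplotype
classification, two-cohort association statistics, a bespoke two-cohort
linkage-disequilibrium (LD) contrast, nonparametric statistics for soluble
HLA-G (sHLA-G), and semiquantitative immunohistochemistry (IHC) scoring.
This note records the statistical model behind each stage, the conventions
chosen where the published tables pinned them down, and what the synthetic
cohort generator does and does not emulate.

## Haplotype model

The HLA-G 3'UTR carries eight polymorphic sites — a 14-bp
insertion/deletion plus seven biallelic SNPs (3003C/T, 3010C/G, 3027A/C,
3035C/T, 3142C/G, 3187A/G, 3196C/G) — whose joint states define named UTR
haplotypes (UTR-1 = DelTGCCCGC, and so on). Chromosomes are classified by
exact motif lookup against a definition table; the built-in set contains
the eleven haplotypes observed in the Sardinian study panel. Sites are
modeled as categorical states, not genomic coordinates: no downstream
statistic uses positions.

Two built-in definitions (UTR-18 and UTR-6) share the printed motif
DelTGCCCAC. Whether this is a typographical duplication or reflects an
unprinted distinguishing site cannot be decided from the available tables,
so the duplicate is retained as printed and surfaced as an *ambiguous*
call; nothing ever silently picks one label. Subject files may carry
lab-resolved label columns, which take precedence over motif lookup, so
datasets with resolved labels (including the generator's output)
round-trip losslessly.

Phasing is out of scope: inputs are resolved per-chromosome motifs, with
classical-HLA alleles optionally phased onto the same chromosome for the
LD analysis.

## Association statistics

For each haplotype key the two cohorts form a 2x2 table of carrier
chromosomes versus the rest (denominator 2N = twice the subject count).
Two P-value conventions coexist, because the source tables demand one and
the methods prose names another:

* **As-published (default):** a pooled two-proportion z-test, with empty
  cells replaced by 0.5 in the numerators. This is the convention that
  reproduces the published frequency-table P values digit for digit
  (verified on all nine UTR rows and several extended-haplotype rows); the
  exact Fisher test does not (e.g. it yields 0.620 where the table prints
  0.549).
* **Exact Fisher** (`p_method="fisher"`): the point-probability two-sided
  rule, tested against a brute-force hypergeometric enumeration oracle.

Odds ratios are oriented as patient odds over control odds. The default
interval is Woolf's logit CI, `exp(ln OR ± z·sqrt(1/a+1/b+1/c+1/d))`, with
0.5 added to *zero cells only*: this, and not the all-cells
Haldane–Anscombe correction, reproduces the published zero-cell row
(OR 0.072, CI 0.004–1.272). The conditional-MLE OR with its exact interval
(the convention of R's `fisher.test`) is available as
`method="conditional"`; it is what reproduces the published DRB1*03:01
allele result, OR 2.29 (1.67–3.15).

Bonferroni correction is `min(1, m·p)`. The multiplier is configurable
because the source is internally inconsistent: `shared_nonzero` (keys
non-zero in both cohorts; the factor 8 of the UTR table), `all_rows` (the
factor 26 of the extended-haplotype table), or an explicit integer. The
default `pc_policy="printed"` multiplies the P value *rounded to three
decimals*, which is evidently how the published corrected values were
produced (8 x 0.001 = 0.008, 8 x 0.019 = 0.152, 8 x 0.018 = 0.144;
multiplying the raw P gives 0.009, 0.150 and 0.143 instead);
`pc_policy="exact"` uses the raw P. Corrected values are reported only for
rows significant before correction, matching the published layout.

## Linkage disequilibrium

For markers A (a UTR haplotype) and B (a classical allele or a partial or
complete multi-locus haplotype) on the same chromosome,

    D  = f_AB − p_A·p_B
    D' = D / D_max,   D_max = min(p_A(1−p_B), (1−p_A)p_B)      if D > 0
                      D_max = min(p_A·p_B, (1−p_A)(1−p_B))     if D < 0

with all frequencies estimated within cohort. The per-cohort test
statistic is reconstructed (the source says only "chi-square test"): the
expected joint count is `round(p_A·p_B·2N)` to the nearest integer, and
the statistic is the Yates-continuity-corrected chi-square of the 2x2
table `[[n_obs, 2N−n_obs], [n_exp, 2N−n_exp]]`. This reconstruction —
with the rounding, and with the continuity correction — uniquely
reproduces all six published statistics checked (46.62, 10.27, 25.52,
12.72 and the two contrast P values); the uncorrected and unrounded
variants do not.

The two cohorts are contrasted **as published**: the difference of the two
1-df statistics is referred to the upper tail of a chi-square with two
degrees of freedom (`P = exp(−Δ/2)` in closed form). This is *not* a
standard distributional result — the difference of two independent 1-df
chi-squares is not 2-df chi-square distributed — so the module labels it
"as-published" and offers a seeded permutation contrast (cohort-label
shuffling, default 10,000 permutations) as a statistically defensible
alternative. A non-positive difference reports P = 1 with a direction
flag.

A note on printed precision: the published LD table evidently computed D
from marginals rounded to four decimals; the package uses exact count
ratios, which agree with every printed value except one control-cohort D
that sits on a 0.005 rounding boundary (7.095 prints as 7.09 there, 7.10
here).

## Soluble HLA-G and clinical statistics

sHLA-G (U/mL, ELISA detection limit 0.6; values below the limit are kept
as reported unless flooring is requested) is right-skewed, so groups are
summarized by the median with a distribution-free Hodges–Lehmann 95%
interval and compared by the Wilcoxon rank-sum test (exact null when the
combined tie-free sample is ≤ 25, otherwise normal approximation with tie
and continuity corrections). The Hodges–Lehmann interval takes the order
statistics of the n(n+1)/2 Walsh averages at ranks from the one-sample
signed-rank null — computed exactly via a subset-sum recursion for n ≤ 50,
by normal approximation above. With k the largest integer whose null CDF
does not exceed α/2, the interval is `[W(k+1), W(M−k)]` (1-indexed); its
coverage is `1 − 2·P0(W+ ≤ k) ≥ 1−α`, verified empirically at n = 50
(theoretical 95.06%, empirical 95.0% over 20,000 replicates) and against
R's `wilcox.test(conf.int=TRUE)` on frozen examples. Samples too small to
attain the requested confidence return the widest attainable interval.

Correlations use Kendall's tau-b with tie correction (exact P for tie-free
n ≤ 10). The clinical baseline table compares continuous variables with an
equal-variance t-test (Welch optional) and mean ± SD with a t-based CI,
and binary variables with Fisher's exact test and a normal-approximation
proportion CI clipped to [0, 100]. The cohort-level subject data behind
the original clinical table are not public, so this module is validated by
enumeration oracles and simulation rather than by reproducing printed
subject-level P values. (The original table's sHLA-G row labels a
median-with-CI as mean ± SD; the report here prints both.)

## Immunohistochemistry scoring

Pathologist-reported percentages of HLA-G-positive cells map to an ordinal
score: 0% → 0 (−); "<25" → 1 (+/−), a distinct borderline sentinel never
coerced to a number; 1–25% → 1 (+); 26–50% → 2 (++); 51–75% → 3 (+++);
76–100% → 4 (++++). Staining intensity is ignored by design. The
procedural description of this scheme in the source text is internally
garbled (it lists five scores against four symbols); the mapping adopted
here is the one attested by all 52 x 4 readings of the packaged biopsy
table, which the scoring golden test reproduces symbol for symbol.
Inter-rater agreement is plain percent agreement, averaged over rater
pairs per variable and then over variables; missing cells drop out
pairwise with a count.

The plasma-cell positivity rate counts biopsies with any positive
plasma-cell staining (borderline included): 36/52 = 69.2% on the packaged
table. A threshold rule relating staining to clinical severity is
mentioned in the source with an apparently misused symbol; it is
documented here but deliberately not implemented as a classifier.

## Synthetic cohort generator

The generator draws the study conditions, not a fitted model:

* **Cohorts:** 205 patients / 210 controls; two chromosomes per subject by
  random union within cohort (Hardy–Weinberg; no family structure).
* **UTR haplotype frequencies:** the published per-cohort counts over
  2N = 410 / 420. Configured maps may sum below 1; the remainder goes to a
  catch-all label carrying a valid motif that matches no definition.
* **Linked marker:** DRB1*03:01 at marginals 0.388 (patients) / 0.217
  (controls), held at target D' = 0.92 / 0.50 with UTR-1 by inverting the
  Lewontin normalization (f_AB = p_A·p_B + D'·D_max, then conditional
  carriage per chromosome). The round trip recovers the target to 1e-12
  across a margin grid. The ancestral A*30:02–B*18:01–C*05:01 block rides
  on a DRB1*03:01-conditional fraction (0.56 / 0.47, the published
  complete-haplotype to allele count ratios); other loci fill from small
  background pools.
* **sHLA-G:** log-normal per stratum, `median = exp(mu)`, log-SD 1.1
  (chosen once from the published median CIs, which imply a log-scale SD
  near 1.2). Stratum medians: controls 21.3; biopsied patients 33.5
  (mild/moderate) and 8.8 (severe); unbiopsied patients 13.9, the
  published cohort-level patient median — biopsy in the emulated study was
  clinically indicated, so the biopsied subset is deliberately not a
  random draw of the cohort. UTR-1 carriers get a multiplicative shift
  (default 1.35), with the stratum location recentered by the expected
  carrier fraction so stratum medians stay near their targets.
* **Biopsy subset:** 52 patients; grades mild/moderate/severe at the
  published 12/12/28 proportions; grades exist only for biopsied subjects.
  IHC plasma-cell positivity is certain under severe inflammation and 1/3
  otherwise, with percent bands matching the packaged table's composition.
  Clinical chemistry (ALT, AST, ALP, gamma-globulin) is log-normal with
  severity-dependent medians.
* **Determinism:** one `numpy` Generator seeded once; identical config +
  seed yields byte-identical subject files.

What passing recovery tests show: the pipeline's estimators (frequencies,
odds ratios on the log scale, D') are unbiased at the study's sample sizes
under the generator's idealized model. What they do not show: robustness
to genotyping error, population stratification, assay noise, or informative
missingness — none of which the generator models. Odds-ratio recovery is
assessed on the log scale (geometric mean of replicates against the
configured truth): the sample OR is a ratio estimator whose Jensen bias at
these counts (~2.5%) is comparable to three Monte-Carlo standard errors at
500 replicates, and the log scale is the standard comparison for ratio
estimators.

## Problem sizes used by the test suite

Simulation-backed checks run at the study's own cohort sizes (205 + 210
subjects): 500 replicate pairs for parameter recovery, 2,000 seeded
replicates at n = 50 for Hodges–Lehmann coverage, exhaustive enumeration
for the small-sample rank-test oracles, and 60-replicate power curves for
the rank-sum monotonicity check. These sizes give Monte-Carlo standard
errors small enough to resolve the calibration targets while keeping the
default suite quick to run.

## Known limitations

* The as-published LD contrast has no valid distributional justification;
  use the permutation contrast for inference on new data.
* The UTR-18/UTR-6 ambiguity is unresolved by design; motif-only inputs
  cannot distinguish them.
* No Hardy–Weinberg testing, covariate adjustment, regression modeling,
  r² or multi-allelic LD statistics, haplotype-phase EM, or upstream
  variant calling: inputs are resolved per-chromosome calls.
* IHC scoring starts from pathologist percentages; there is no image
  analysis.
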