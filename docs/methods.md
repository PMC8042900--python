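# Methods

This note documents the statistical procedures, the generator that stands in
for real data, the numerical choices, and the known limitations of
`codoncontrib`.

## Sequence features

The unit of analysis is the gene, represented by one transcript (the
longest-CDS isoform by default; ties broken by transcript id). Coordinates
follow GFF3: 1-based, inclusive, with minus-strand sequences
reverse-complemented so position 1 is always the 5′ end. When an annotation
lacks explicit UTR rows, UTRs are inferred as the exonic region outside the
CDS in transcript orientation.

Codon frequencies are in-frame proportions over the CDS: count(codon) /
total counted codons, with codons containing N removed from both numerator
and denominator, and all 64 codons reported (zero-filled). Stop codons count
toward codon usage but are excluded from the amino-acid denominator, so the
20 amino-acid frequencies sum to 1 over coding positions. Base frequencies
are per region (CDS, 5′UTR, 3′UTR) over non-N bases; GC = (G+C)/(A+C+G+T);
length is the raw region length including N. Transcripts whose CDS length is
not divisible by 3 are flagged at load and never reach codon-level features.

The default registry is 103 features: 64 codons + 20 amino acids + 4 bases ×
3 regions + GC × 3 + length × 3 + the transcript fold change. The registry
is configurable; the count is reported rather than forced to any particular
total, since reasonable registries differ in whether they include stop
codons, CDS GC, or total length. Genes lacking a UTR get that region's
base/GC features imputed with the column mean over genes that have the
region (length 0), recorded in the assembly report; this keeps the design
matrix complete without pushing the gene toward an extreme composition.

## Fold changes and differential calls

Fold change is mean(treatment replicates) / mean(control replicates).
A gene that is all-zero in both conditions is excluded and flagged; a zero
control mean is stabilized by adding half the smallest nonzero abundance of
the table to both means (flagged). Transcript significance uses a Welch
t-test on log2(FPKM + 1) — a deliberate simplification standing in for
count-based differential machinery, matched by the generator, whose
replicate noise is log-normal; the contract of interest is the thresholding
logic. DET: FC > 2 or < 1/2 and BH q < 0.05 (BH computed over all quantified
transcripts). DEP: pooled-variance two-sample t-test on log2 intensities,
p < 0.01, no FDR; Welch available by argument. Degenerate rows (zero
variance, equal means) get p = 1.

Protein tables follow the four-replicate TMT reliability rule, applied per
condition: at least 3 of 4 replicates observed in every condition entering a
contrast, a single missing value imputed with the mean of the other three,
then per-sample median scaling to the grand median of the imputed matrix.
Imputation never alters an observed value.

## Correlation screen

Pearson r of each feature against the raw protein fold change (log2 by
option), two-tailed p from the t transform with n − 2 df, starred at 0.05 /
0.01. Constant features report r = 0, p = 1, with a flag.

## MARS and the contribution decomposition

The forward pass adds hinge *pairs* max(0, x − t), max(0, t − x). Candidate
knots are the interior distinct observed values (a pair at an interior knot
already spans the linear term, so separate linear candidates are
unnecessary; for two-valued features the lower value is used). Features with
more than `max_knots` (default 64) distinct values use a quantile-indexed
subset of observed values. Every candidate is scored by its exact joint RSS
decrease via projection against the orthonormalized current basis, computed
with sorted suffix sums (O(n · terms) per feature per step). Ties break to
the lowest feature index, then the smallest knot. Redundant columns (e.g.
the partner hinge of a second pair on an already-linear-spanned feature) are
dropped silently at the QR check. The pass stops at `max_terms` (default 21,
counting the intercept) or when the best improvement falls below
`forward_tol` × TSS (default 1e-4).

The backward pass removes, at each size, the term whose removal least
increases RSS, and selects the size minimizing GCV with
C(k) = k + penalty·(k−1)/2 (penalty 2 for additive models, 3 when
`degree` > 1 allows product terms). Sizes with C(k) ≥ n are inadmissible and
skipped with a warning. The default is additive (`degree` = 1): it keeps the
pie-chart attribution well defined; interactions remain available.

Variable importance follows the pruning trace up to the selected size:
`nsubsets` counts subsets containing the feature; RSS (and GCV) importance
sums the criterion decrease attributed to the term(s) that re-introduce the
feature along the trace, floored at zero.

The contribution report is an attribution *decision*, not an estimate with
its own sampling theory: feature contribution = (RSS-importance share) ×
R² × 100. Categories sum over member features, so category contributions
add to the total explained percentage and explained + unexplained = 100
exactly. A GCV-based share is selectable.

The response is log2 fold change by default: fold-change noise is
multiplicative, and on the log scale the planted generator model is linear,
so "explained variance" has a single consistent meaning across the
generator, the MARS fit and the verification fits. Raw-scale fitting is
available.

## Verification fits

The elastic net (mixing 0.5, 60-point geometric λ path, 10-fold seeded CV)
is solved by cyclic coordinate descent on the Gram matrix with warm starts
and an active-set inner loop. Convergence uses two rules: max coefficient
update ≤ 1e-7, or relative objective decrease ≤ 1e-9 per sweep — the second
ends the slow flat-direction crawl that exactly collinear columns produce at
small λ (compositional blocks: codon, amino-acid and base frequencies each
sum to one). Coefficients are reported on the original scale.

OLS cannot absorb those exact collinearities, so the verification OLS runs
on the MARS-selected features; rank deficiency is still checked by pivoted
QR and reported by column name. The agreement table covers the union of
features selected by any method (MARS term; elastic-net nonzero; OLS
p < 0.05) and compares effect signs, where the MARS sign is the sign of the
correlation between a feature's partial prediction and the feature itself.

## Group statistics

Kruskal–Wallis is computed from mid-ranks with the tie correction
1 − Σ(t³ − t)/(N³ − N); H is 0 and p is 1 when every value is identical.
p comes from the chi-square distribution with k − 1 df; a seeded permutation
p (with add-one correction) is available and recommended when any group has
fewer than 5 members. Group assignment uses fold change > 1.2 / < 0.83 with
BH q < 0.05 by default (raw p selectable); the whole-genome group can be the
full catalog rather than only genes with fold changes.

## Enrichment

The upper tail P(X ≥ k) of the hypergeometric distribution is summed in log
space (gammaln + logsumexp). Only terms with k ≥ 1 enter the BH family;
`passes_filter` applies k ≥ 7 and q < 0.05 by default (both configurable,
e.g. stricter count/q rules for large screens). The universe defaults to the
genes present in both the annotation and the feature matrix. No ontology
propagation is performed — the method is flat by design.

## Synthetic data generator

The generator emulates the statistical shape of a heat-stress
transcriptome + proteomics study so that recovery of known, planted
structure is the acceptance standard:

* **Catalog** — `n_genes` single-exon genes, one per contig, random strand;
  CDS = ATG + interior codons drawn from sense-codon weights (uniform by
  default) + a random stop; CDS length normal (default mean 300, sd 75
  codons — a typical plant mRNA scale), UTR lengths normal (120 ± 40 and
  250 ± 80 nt), UTR bases uniform. A fraction (default 10 %) of genes has
  its interior AAG probability raised by 0.05, giving a clearly separated
  AAG-rich subset while remaining within the range of real codon bias.
* **Expression** — per treatment, transcript log2 fold changes are
  N(0, 1); the protein log2 fold change is Σ β_j z(feature_j) + ε with
  standardized defaults β = 0.5 (transcript fold change) and 0.4
  (AAG frequency), and ε solved so the planted predictor explains a target
  R² of 0.6. Replicate tables multiply a log-normal baseline (log2 means 4
  and 14 for FPKM-like and reporter-like scales) by 2^(effect) and
  log-normal replicate noise (sd 0.25 in log2); three transcript and four
  protein replicates per condition. Protein values go missing completely at
  random (entry rate 10 %), never more than one per gene-condition, so the
  reliability filter's drop path is exercised separately via custom masks.
  Setting `transcript_fc_sd = 0` and `noise_sd = 0` yields a true global
  null for calibration experiments.
* **Ground truth** — betas, per-treatment noise sd and realized R²
  (var(pred)/var(pred + ε) of the actual draw), the boosted gene set, and
  all planted fold changes, recorded before noise is discarded and
  reproducible bit-for-bit from (spec, seed). One seed stream is split into
  named substreams (sequences, fold changes, noise, missingness,
  annotation).

What the generator does *not* emulate: read-level counting noise
(transcript "FPKM" error is log-normal, not negative-binomial), isoform
complexity and multi-exon splicing variability (exercised only by
hand-built fixtures), peptide-to-protein inference artifacts,
non-random missingness (real TMT missingness is intensity-dependent), and
correlated feature structure beyond what codon sampling induces. Passing
recovery tests therefore demonstrates that the pipeline's estimators and
attributions are correct under a known model of the right shape — not that
any particular biological dataset satisfies that model.

The estimated protein fold change carries replicate noise on top of the
planted value, which dilutes the recoverable R² by a few percentage points;
the ±10-point recovery band absorbs this.

## Problem sizes

Defaults were chosen as the package's standing study conditions: n = 3000
genes for recovery runs (20 seeds), 1000 genes for null-calibration runs,
and a 150-gene catalog for end-to-end pipeline fixtures. The complete
enumeration check for the hypergeometric tail covers every instance with
N ≤ 50; Kruskal–Wallis calibration uses 10⁵ permutations at 3 × 40
observations.

## Known limitations

* The MARS forward pass subsamples knots above `max_knots`; exactness
  against enumeration holds when all distinct values are candidates.
* Backward elimination is greedy; it provably matches exhaustive GCV subset
  search only on well-separated instances (verified on such instances).
* The contribution attribution is one defensible rule among several; with
  strongly correlated selected features, importance splitting is
  order-dependent, as in any greedy selector.
* Per-condition application of the ≥3-of-4 rule is stricter than an
  any-condition reading; the choice is recorded in the imputation report.
* The transcript differential test is a log-scale t-test, not a
  count-model test; DET calls on real count data will differ near the
  significance boundary.
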