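# codoncontrib

**Which sequence features drive rapid protein-abundance changes?**

When an organism meets sudden stress — a grain-filling crop moved into heat,
yeast shifted to 37 °C — some proteins change abundance within an hour, often
without a matching change in their transcripts. `codoncontrib` is a pipeline
for quantifying what *does* predict those rapid protein changes: the change
in transcript abundance, and static features of the transcript itself —
codon usage (notably the lysine codon AAG), amino-acid frequencies, base and
GC composition of the CDS and UTRs, and region lengths.

It is aimed at researchers with matched transcriptome (FPKM-like) and
proteomics (TMT reporter-intensity) tables plus a genome annotation, who want
a reproducible, tested answer to "how much of the protein fold-change
variance does each feature class explain?".

## What it computes

Writing the protein fold change of gene *g* under a treatment/control
contrast as FC_g = mean(treatment)/mean(control), the core model is a
multivariate adaptive regression spline (MARS) fit

    log2 FC_g  =  β₀ + Σ_m β_m B_m(x_g) + ε_g,

where each basis term B_m is a hinge function max(0, x_j − t) / max(0, t − x_j)
of one feature x_j with knot t at an observed value, built by a greedy
forward pass and pruned backward under generalized cross-validation,

    GCV(k) = (RSS_k / n) / (1 − C(k)/n)²,    C(k) = k + penalty·(k − 1)/2.

Per-feature RSS importances from the pruning trace are converted into a
variance-contribution report: feature share × R² × 100, summed into category
contributions (transcription, codon usage, amino-acid frequency, base
composition, GC, length), with the remainder to 100 % reported as
unexplained. The fit is cross-verified by OLS (on the selected features) and
an elastic net (coordinate descent over a λ path with k-fold CV), with a
sign/selection agreement table.

Around that core the package provides the full pipeline:

* `annotation_io` — FASTA + GFF3 → spliced, strand-correct CDS/5′UTR/3′UTR
  sequences (explicit or exon-minus-CDS-inferred UTRs, longest-CDS isoform
  collapse);
* `sequence_features` — the 103-feature registry (64 codons, 20 amino
  acids, base/GC/length per region, transcript fold change);
* `expression` — replicate tables → fold changes with differential calls
  (DET: FC > 2 and BH q < 0.05; DEP: t-test p < 0.01) and the ≥3-of-4
  TMT reliability/imputation rule;
* `group_stats` — tie-corrected Kruskal–Wallis comparison of a feature
  (canonically AAG frequency) across whole-genome / identified /
  up- / down-regulated gene groups;
* `enrichment` — log-space hypergeometric term enrichment with BH FDR and
  count/q filters, including AAG-rich gene-set selection (frequency > 0.08);
* `synthetic_data` — a generator that plants known effects (codon
  composition boosts, linear-plus-noise protein responses) and records the
  ground truth, so every stage is testable without external data;
* a `codoncontrib` CLI orchestrating all stages with checksum-based caching.

## Worked example

```python
from codoncontrib import SimulationSpec
from codoncontrib.synthetic_data import simulate_study
from codoncontrib.workflow import analyze_study

spec = SimulationSpec(n_genes=1000, seed=11)   # plants beta=0.5 on transcript_fc, 0.4 on codon:AAG
study = simulate_study(spec)
analysis = analyze_study(study, "30C", seed=11)
print(analysis.results.summary())
```

prints

```
Factor contribution analysis
==============================================================
genes: 1000    features: 103    response: protein fold change (log2)
MARS R-squared: 0.5448   GCV: 0.34397   terms: 13
--------------------------------------------------------------
Category contributions (% of protein variation):
  transcript       30.0%
  codon            22.9%
  base              0.9%
  amino_acid        0.6%
  unexplained      45.5%
--------------------------------------------------------------
Top features:
  transcript_fc      transcript     30.0%
  codon:AAG          codon          21.7%
  base:G:cds         base            0.6%
  ...
Significant correlations at 0.01 (two-tailed): 6
Verification: 30/30 features with consistent signs across MARS/OLS/elastic net
==============================================================
```

Reading it: the generator planted standardized effects of 0.5 (transcript
fold change) and 0.4 (AAG frequency) with noise set for R² ≈ 0.6; the
realized R² of this draw was 0.617. The fitted decomposition attributes
30 % of protein variation to transcription and 23 % to codon usage — almost
all of it to `codon:AAG` — with the two planted drivers ranked first and
second and all three regression methods agreeing on effect signs.

The same analysis runs from the shell on files:

```bash
codoncontrib simulate --out-dir sim/ --seed 11
codoncontrib run --config run.yaml        # features -> foldchange -> associate -> groups -> enrich
```

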