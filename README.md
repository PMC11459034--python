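# compmut — composite somatic mutations in tumor cohorts

`compmut` analyzes **composite mutations**: two or more independent
driver-level genetic hits accumulating in the *same* gene of the *same*
tumor — e.g. a melanoma carrying both BRAF V600E and V600M, or a lung
adenocarcinoma with EGFR T790M on top of L858R. Composite mutations are a
footprint of ongoing molecular evolution and a candidate early marker of
therapy resistance. The package is aimed at cancer-genomics analysts working
with cBioPortal-style cohort exports (MAF mutation tables plus gene-level
GISTIC copy-number calls).

## What it computes

1. **Composite calling.** A driver-level event is a hotspot mutation from a
   curated catalog or a high-level copy-number call (deep deletion −2 /
   amplification +2). A gene in a sample is called composite with ≥2 events
   (oncogene) or ≥3 events (tumor suppressor). Within composite-bearing
   tumors, driver events in other genes are *co-mutations*; everything below
   the driver level is background.
2. **Co-mutation enrichment.** Per tumor type and composite gene *g*,
   samples split into composite vs non-composite groups and each co-gene is
   tested on its 2×2 presence table with a two-sided Fisher's exact test
   (selection at raw P < 0.05; cross-product odds ratio *ad/bc*). A
   frequency threshold of 1.04 × the stratum's background mutation rate
   (median per-gene mutation frequency) flags co-genes above the tumor-type
   mutation burden. The *complementary relationship* is the Pearson
   correlation between each co-gene's frequency in the composite vs
   non-composite context.
3. **Chromosomal disruption ("chromosysmos").** The fraction of co-mutation
   events on the composite gene's chromosome, against a baseline expectancy
   of 1/24 ≈ 4.2% per chromosome, with an empirical p-value from a
   randomization null that replaces composite genes with random sham driver
   genes. Inter-gene distances use concatenated-genome coordinates
   (karyotype order, gene midpoints) normalized by the total genome distance
   3×10⁹ bp.
4. **Prediction.** Per composite gene, two feature blocks over the
   *significant* co-genes — binary event presence, and normalized distance
   to the composite gene (sentinel 1.0 when absent) — each train a
   100-tree random forest on a stratified 2/3–1/3 split. Class
   probabilities combine as a weighted ensemble,
   `score = 0.75·P_binary + 0.25·P_distance`, the larger class score wins
   (exact ties → non-composite), and performance is reported as the
   confusion matrix, accuracy, balanced accuracy = (TPR + specificity)/2,
   precision, TPR/FPR, the ROC step curve and its trapezoidal AUC, plus a
   10-step feature-shuffling robustness sweep (10%…100%).
5. **Synthetic cohorts.** A seeded generator plants all of the above —
   composite prevalence (default 5%), co-gene odds ratios, same-chromosome
   placement probability (default 35%), per-tumor-type background rates, a
   C>T-heavy substitution spectrum — and returns the ground truth, so every
   analysis step is testable by parameter recovery.

## Worked example

`examples/01_call_composites.py` builds a three-sample cohort and calls
composites:

```
composite calls (>=2 events for oncogenes, >=3 for tumor suppressors):
sample_id gene     role  n_events                                        events
  LUAD-02 EGFR oncogene         2 hotspot_mutation:L858R;hotspot_mutation:T790M
   MEL-01 BRAF oncogene         2 hotspot_mutation:V600E;hotspot_mutation:V600M

prevalence: 2/3 samples (67%) carry a composite mutation
```

Both planted double-hit genes are called; the third sample's single KRAS
hotspot stays below the threshold. `examples/04_predict_composites.py`
trains the ensemble on a synthetic 1500-sample lung cohort with six co-genes
planted at odds ratio 8:

```
held-out test set: 501 samples
confusion matrix: TP=14 FP=2 TN=475 FN=10
accuracy 0.976 | balanced accuracy 0.790 | precision 0.875 | TPR 0.583 | FPR 0.004
ROC AUC (trapezoidal over the score sweep): 0.965
...
   10% shuffled -> AUC 0.961
  100% shuffled -> AUC 0.552
```

The AUC of 0.965 reflects the planted co-mutation structure; fully shuffled
features drop the model to chance, confirming the signal is not an artifact
of the training procedure. The other examples cover Fisher co-mutation
selection (`02`), same-chromosome enrichment with its randomization test
(`03`, observed 33.4% vs 4.2% baseline, empirical p ≈ 0.001), and the full
pipeline with its manifest (`05`). A thin CLI mirrors the chain:
`compmut simulate | call-composites | comut-stats | chrom-disruption |
run-all`.

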