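# cnvlnc

Somatic copy-number alterations (SCNAs) recurrently amplify or delete genomic
regions in tumors, and long non-coding RNAs (lncRNAs) inside those regions can
be dosage-driven into over- or under-expression with real consequences for
disease progression. `cnvlnc` implements, as a tested and reusable Python
library plus CLI, the multi-stage screen that finds such **SCNA-driven
lncRNAs** in a paired tumor/normal cohort, together with the downstream
statistics used to characterize a hit: co-expression networks, gene-set
over-representation, clinicopathological association, survival analysis, and
a handful of deterministic assay quantification formulas (ISH scoring, tumor
volume, mRNA decay half-life, AU-rich-element scanning).

It is aimed at computational cancer biologists who have per-sample
copy-number segment tables (SEG-like TSV), probe-level paired expression
matrices, gene/probe annotation, and clinical tables — and who want the whole
funnel from raw inputs to a candidate table to be scripted, thresholded
explicitly, and reproducible.

## The screen

1. **Paired differential expression.** Per probe, the log2 fold change is the
   mean of per-patient tumor−normal differences, tested with a two-sided
   paired *t*-test and Benjamini–Hochberg adjusted across probes. A probe is
   *up* when log2FC ≥ 1 and adjusted *p* ≤ 0.05 (symmetric for *down*).
2. **Focal copy-number calls.** Each segment carries a segment mean
   SM = log2(CN/2); focal gains are SM > 0.3, losses SM < −0.3 (strict).
3. **Recurrence.** A breakpoint sweep counts, at every base, the samples whose
   called events of one direction cover it, and emits maximal runs with an
   identical supporting-sample set and support ≥ 2 (of the cohort).
4. **Directional concordance.** A DE lncRNA probe is retained iff its gene's
   interval overlaps (≥ 1 bp) a recurrent region of the concordant direction
   (up ↔ gain, down ↔ loss).
5. **Probe-support aggregation.** Genes with ≥ 2 concordant ("indicative")
   probes, all in one direction, become candidate SCNA-driven lncRNAs;
   direction conflicts are dropped and logged, and an explicit exclude list
   removes already-characterized lncRNAs after counting.

Downstream, candidate lncRNAs are correlated against DE-filtered mRNAs
(Pearson *r*, *p* from *t* = *r*√((n−2)/(1−*r*²)), edges at |*r*| ≥ 0.7 and
BH-adjusted *p* < 0.05), correlated gene sets are tested by upper-tail
hypergeometric over-representation against user-supplied GMT collections, and
patients dichotomized at the median candidate expression are compared by
Pearson χ², Kaplan–Meier/log-rank, and Cox proportional-hazards regression
(HR with Wald 95% CI).

A first-class synthetic cohort generator (`cnvlnc.simulate`) produces the
whole study — segments with planted recurrent regions, dosage-driven
expression, co-expression structure, clinical covariates and survival tied to
the planted drivers — with a truth table, so every stage is verifiable
without external data.

## Worked example

```python
from cnvlnc import SimulationConfig, simulate_cohort, run_screen, km_fit

cohort = simulate_cohort(SimulationConfig(seed=1))   # 9 patients, 10 planted drivers
report = run_screen(cohort.expression, cohort.pairing, cohort.profiles,
                    cohort.genes, cohort.probe_map)
for key, value in report.stage_counts.items():
    print(f"{key}: {value}")
```

prints the stage funnel:

```
n_probes: 2505
n_de_probes: 83
n_de_lnc_probes: 29
n_de_lnc_genes: 10
n_gain_regions: 8
n_loss_regions: 8
n_up_in_gain_probes: 15
n_down_in_loss_probes: 14
n_concordant_genes: 10
n_conflict_genes: 0
n_unmapped_probes: 0
n_candidates: 10
```

Of 2505 probes, 83 are differentially expressed; 29 of these belong to
lncRNAs, 15 up-probes fall in recurrent gain regions and 14 down-probes in
recurrent loss regions, and probe-support aggregation leaves 10 candidates —
here exactly the 10 planted drivers, with zero false positives:

```
gene_id direction  n_probes                 region  region_support
LNC0018        up         4 chr2:44419443-47684945               9
LNC0025      down         4 chr3:10883768-12069830               9
LNC0055        up         3 chr1:53628262-57097093               9
recovered 10/10 planted drivers, 0 false positives
```

Survival at nine patients is deliberately underpowered (the same cohort gives
log-rank p = 0.689); at a cohort size where survival analysis is meaningful
the planted hazard ratio of 3.7 between driver-high and driver-low patients
is recovered:

```python
cfg = SimulationConfig(seed=1, n_patients=120, n_lnc_genes=30, n_mrna_genes=60,
                       n_driven_lnc=4, coexpression_targets_per_driver=2,
                       n_gain_regions=4, n_loss_regions=4)
clin = simulate_cohort(cfg).clinical
# log-rank chi2 = 40.92, p = 1.58e-10
# Cox: HR = 3.917 (95% CI 2.516-6.098), p = 1.49e-09
```

The same pipeline is available from the shell:

```
cnvlnc simulate --out cohort/ --seed 1
cnvlnc screen run --indir cohort/ --out screen_out/
cnvlnc survival km cohort/clinical.tsv
cnvlnc quant volume 10 5          # -> 125
cnvlnc assoc chi2 32 14 14 32 --rows 2
```

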