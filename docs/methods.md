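# Methods

## Model and pipeline

The package treats a tumor genome as a set of per-sample copy-number
segments, each carrying a segment mean SM = log2(CN/2) (0 diploid, +1 one
doubling, −1 hemizygous loss), and a paired tumor/normal probe-level log2
expression matrix. The screen asks a single question per lncRNA: is its
differential expression *directionally concordant* with a *recurrent* focal
copy-number event at its locus, with independent probe support?

Stages and their contracts:

- **Paired DE** (`cnvlnc.de.paired_de`): per probe, log2FC = mean of
  per-patient tumor−normal differences; two-sided paired *t* on the
  differences (requires ≥ 3 pairs); Benjamini–Hochberg across all tested
  probes. Thresholds are inclusive (log2FC ≥ `fc_thr`, adjusted p ≤ `alpha`).
  Zero-variance differences are flagged `degenerate` (p = 0 if the mean
  difference is non-zero, else 1) rather than propagating NaNs.
- **Focal calls** (`cnvlnc.segments.call_focal_events`): strict inequalities
  at ±0.3 — a segment exactly at a threshold is neutral, following the
  convention's wording ("> 0.3", "< −0.3").
- **Recurrence** (`recurrence_map`): an exact breakpoint sweep. At every
  base, the set of samples whose called events of the given direction cover
  it; maximal runs with identical supporting sets and support ≥ `min_support`
  are emitted. This makes the output canonical: regions of one direction are
  disjoint, sorted, and reconstruct the coverage function. It is a deliberate
  simplification of GISTIC-class callers — no background model, q-values or
  peak deconvolution — chosen because the screen only needs "where and in how
  many samples", and because it admits a per-base brute-force oracle that the
  test suite checks against exactly.
- **Concordance** (`cnvlnc.screen`): probes inherit their gene's interval
  (probe-level genomic coordinates are often absent from array annotations);
  ≥ 1 bp overlap with a concordant region retains the probe. Genes with
  ≥ `min_probes` concordant probes in one direction become candidates; genes
  passing in both directions are conflicts and are excluded (such cases are
  rare in practice; excluding is the conservative choice).
  The exclude list (already-characterized lncRNAs) is applied after counting,
  so funnel counts remain comparable.
- **Per-gene CNV status** (`gene_cnv_status`): length-weighted mean SM over
  the gene body with uncovered bases contributing 0, then thresholded. The
  weighted mean is robust to sliver overlaps at segment boundaries; an
  `overlap_rule="any"` alternative is kept for sensitivity analyses.

Downstream statistics are standard and delegated to mature implementations
behind this package's interfaces: Pearson χ² (scipy, no continuity correction
by default, Yates behind a flag), Kaplan–Meier and log-rank (lifelines), Cox
partial likelihood (statsmodels `PHReg`; Breslow ties by default because its
formula is the simplest to verify against a hand-written partial likelihood,
Efron behind a flag), BH (statsmodels), hypergeometric tails (scipy). Wald
95% CIs, exp(β ± 1.96·SE). Network p-values use the exact t transform of
Pearson r with n−2 df, BH-adjusted within each lncRNA's family of tests (the
family definition is a choice; per-lncRNA keeps a candidate's edge list
self-contained). Whether the R ≥ 0.7 edge filter should be applied to signed
or absolute correlation varies between studies; the default is |r| with a
`positive_only` flag.

## Default thresholds

| parameter | default | unit | role |
|---|---|---|---|
| `fc_thr` | 1.0 | log2 | paired-DE fold-change cut |
| `alpha` | 0.05 | — | adjusted-p cut (DE), edge and ORA significance |
| `amp_thr` / `del_thr` | +0.3 / −0.3 | SM (log2) | focal gain/loss calls |
| `min_support` | 2 | samples | recurrence (≥ 2 of the cohort) |
| `min_probes` | 2 | probes | indicative-probe rule per candidate |
| `r_thr` | 0.7 | Pearson r | co-expression edge threshold |

Unpaired (treated-vs-control) DE defaults to |log2FC| ≥ log2(1.5) at raw
p < 0.05 with Welch *t*, the convention for the overexpression comparison it
models; adjustment is available behind a flag.

## Synthetic cohort generator

`simulate_cohort` emulates the nine-patient paired design the screen targets:

- **Segments.** `n_gain_regions` + `n_loss_regions` planted intervals
  (1–4 Mb) on a four-chromosome 180 Mb toy genome, mutually disjoint. Each
  region is carried by a random subset of tumors; integer copy numbers
  (gains from {3,4,5}, losses 1) are converted through SM = log2(CN/2).
  Two private (support-1) events per sample add non-recurrent background.
- **Driver penetrance.** Regions hosting planted drivers draw their support
  from {n−1, n}; background regions draw uniformly from
  {`region_recurrence`, …, n}. This is forced by the screen's own
  arithmetic: a driven gene shifted by `dosage_effect` only in carrier
  samples has paired log2FC ≈ (k/n)·`dosage_effect`, so with effect 1.5 and
  an |log2FC| ≥ 1 cut only k ≥ 6/9 events are visible at all and only near
  -ubiquitous ones reliably. Biologically this mirrors the broad, high-
  frequency chromosome-arm gains in which screens of this kind find their
  hits.
- **Expression.** Generated directly on log2 scale (the pipeline works in
  log fold changes throughout; no raw-intensity model). Gene baselines
  N(8, 1.5²), probe offsets N(0, 0.25²), i.i.d. noise N(0, `noise_sd`²) per
  sample with `noise_sd` = 0.4. Driven lncRNAs get ±`dosage_effect` (1.5) in
  carrier tumors only; drivers carry 2–4 probes (background genes 1–4) so
  planted truth is recoverable under the ≥ 2-probe rule. Each driver has
  `coexpression_targets_per_driver` target mRNAs whose tumor expression
  shares the driver's standardized profile at correlation
  `coexpression_strength` (0.8) and shifts in proportion to the dosage
  effect (`target_response` = 2/3 log2 per log2, i.e. |FC| = 2 at the
  default dosage; zero dosage ⇒ zero downstream response, which keeps the
  global-null cohort genuinely null).
- **Clinical.** A per-patient driver-activity score (direction-signed mean
  of z-scored driver tumor expression) is median-split; survival is
  exponential proportional hazards with `survival_hr` (3.7, the scale of the
  univariate hazard ratio the screen's motivating hit shows) between
  driver-high and driver-low, median baseline survival 36 months,
  independent exponential censoring tuned to `censoring_rate` plus a
  120-month horizon. Metastasis status follows a logistic link with odds
  ratio `metastasis_odds_ratio` (3.0) for driver-high patients — the
  association is attested but no generative model is published, so this is
  an explicit stand-in.
- **Randomness.** One master seed; named `SeedSequence` substreams per
  component (regions, segments, annotation, expression, clinical, gene
  sets), so extending one component cannot perturb the others. Fixed seed ⇒
  byte-identical files.

What the generator does **not** emulate: microarray intensity/normalization
artifacts, count-based RNA-seq noise, batch effects, allele-specific copy
number, or correlated noise between neighboring genes. Passing tests
therefore demonstrate correctness of the screen's logic and calibration of
its statistics under a clean generative model — not robustness to the
technical structure of real array or sequencing data.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open internally; SEG files are 1-based
  inclusive on disk and converted only at the I/O boundary; BED stays native.
  Strand is ignored for CNV overlap (copy number is strandless).
- No maximum segment length is imposed on "focal" events by default; the
  recurrence sweep is length-agnostic and a cap would be arbitrary.
- Dichotomization assigns the median to the low group; there is no single
  high/low cutoff convention in the survival literature, so the choice is
  flagged here deliberately and the rule is pluggable (quantile, fixed).
- Cox fits with non-finite or exploding coefficients (monotone likelihood /
  perfect separation) return `converged=False` rather than silent output.
- The decay model is a single exponential fit by least squares on
  ln(abundance) vs time after normalizing to t = 0; k = −slope,
  half-life = ln2/k, inputs with k ≤ 0 are flagged non-decaying. Multiplying
  all abundances by a constant leaves k unchanged.
- ARE detection is bare AUUUA pentamer clustering with ARED-style classes
  (number of overlapping pentamer starts); the 13-bp ARED-Plus pattern
  variants are not reproduced. Mutation applies A→C and U→G (T→G on DNA
  input) inside hit spans only; by construction the mutated motif CGGGC
  contains no AUUUA, so a re-scan of mutated spans is empty.
- ISH percentages are rounded to the nearest integer before binning, closing
  the rubric's printed gap between 5% and 6%.

## Problem sizes in the acceptance script

`scripts/acceptance.py` uses: 50 cohort seeds × 10 planted drivers for
recovery/FDP; 300 null replicates (60-patient cohorts) for DE and log-rank
calibration; 500 replicates of n = 100 exponential cohorts for Cox recovery
and CI coverage; 100 replicates for decay half-life. These sizes give
Monte-Carlo standard errors comfortably inside the bands being checked while
keeping a full run under a minute.

## Known limitations

- The DE engine is a plain paired/Welch *t*-test, not a moderated
  (limma-class) statistic; probe-count outputs on real array data will not
  numerically match analyses that used moderation.
- The published distal-metastasis contingency row (counts 42,35 / 4,11,
  printed P = 0.019) reproduces under neither plain Pearson χ²
  (χ² ≈ 3.90, p ≈ 0.048) nor Yates-corrected χ² (p ≈ 0.090); the variant
  behind the printed value is unknown, and this package does not guess. The
  lymph-node and TNM rows do reproduce their printed bounds under plain
  Pearson χ².
- Candidate ranking beyond probe support (e.g. pathway-informed selection of
  a single lncRNA for follow-up) is out of scope; the screen emits all
  candidates with support metadata.
- Mean hazard-ratio summaries over replicates carry the upward Jensen bias
  of averaging exp(β̂); the geometric mean is closer to the true HR. The
  acceptance script reports the arithmetic mean, which stays within 10% of
  truth at the simulated sizes.
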