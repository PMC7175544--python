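# Methods

`cfcna` analyses somatic copy-number alterations (CNAs) in cell-free DNA
(cfDNA) from shallow whole-genome sequencing, starting from bin-wise
normalized log2 coverage ratios.  This note records the statistical model,
the choices made where the design was genuinely open, and what the
synthetic cohort generator does and does not emulate.

## Copy-number model

The genome is partitioned into fixed-width bins (100 kb).  For a sample
with tumor fraction f, a region present at k copies in the tumor clone has
expected log2 ratio

    r(f, k) = log2( (2(1 − f) + k·f) / 2 ),

the mixture of diploid germline DNA and the aberrant tumor contribution.
Amplitudes are therefore bounded by the tumor fraction: a single-copy gain
at f = 0.4 sits at log2(1.2) ≈ 0.26, not at log2(1.5).  Bins carry
Gaussian noise with bin-specific variance; bins without reliable
information (centromeric regions, zero-variance panel bins) are masked and
ignored everywhere.

## Segmentation

Stretches of expected equal copy number are found per chromosome with a
circular-binary-segmentation-style recursion: the arc (contiguous run of
bins) maximizing the pooled two-sample t statistic against its complement
is tested by a within-chromosome permutation null; the split is accepted
when p < alpha (default 0.01, 1,000 permutations) and the search recurses
into the resulting pieces.  Choices:

- masked/missing bins are compacted out, never interpolated;
- ties on the statistic break toward the leftmost split;
- chromosomes with fewer than `min_bins` (3) usable bins form one
  untested segment;
- the permutation p-value is evaluated sequentially: permutations stop
  early once the exceedance count alone guarantees p > alpha.  The
  accept/reject decision is identical to running all permutations; only
  clearly null splits exit early.
- the pruning/undo heuristics of the classical DNAcopy implementation are
  not reproduced; at the noise levels and segment sizes simulated here
  they change little.

The inner O(N²) arc scan is compiled (numba), which keeps the ~10,000
profile segmentations of the calibration experiment within minutes on one
CPU.

## Segmental Z-scores and aberration calls

A segment's Z-score standardizes the case's weighted mean ratio over the
segment against the distribution of the same weighted mean across a panel
of p healthy controls:

    Z = ( μ_w(case) − mean_p μ_w(control) ) / sd_p μ_w(control)

with per-bin weights w_i shared between case and controls.  Weights are
the reciprocal of the per-bin population standard deviation across the
panel ("normal variability"): noisier bins count less.  Bins with zero
panel spread are masked; segments whose control means have zero spread are
flagged undeterminable and excluded.  Spread estimators use the population
convention (divide by p) for both weights and the Z denominator; the
normal fit of control CPA scores (below) uses the sample convention
(ddof = 1), the standard choice when fitting a distribution.

Calls follow the |Z| ≥ 3 rule: gain at Z ≥ +3, loss at Z ≤ −3 (boundary
inclusive), neutral otherwise.

## CPA score and abnormality calling

The copy number profile abnormality (CPA) score condenses a profile of n
segments into one tumor-burden number:

    CPA = Σ_i |Z_i| · l_i / n,     l_i in units of 100 Mb.

The per-100-Mb length convention is adopted so that typical scores fall in
the 0–10 range.  Note the score divides by the segment count, so it is not
invariant to how finely a profile is segmented (splitting every segment in
half at unchanged Z halves the score); this sensitivity is inherent to the
definition and documented rather than patched.

Abnormality is called against the control population: a normal
distribution is fitted to control CPA scores and the cutoff placed at its
(1 − FDR) quantile (FDR = 0.01 by default); samples strictly above the
cutoff ("crossing the limit") are abnormal.  Normality of the control
scores is checked with a Lilliefors test whose p-value comes from a
Monte-Carlo null (parameters re-estimated per replicate), since the
composite null invalidates the plain Kolmogorov–Smirnov table.  Liquid and
FFPE profiles are calibrated separately — FFPE noise depresses Z-scores
and with them the whole CPA scale.

A caveat the reference experiments quantify honestly: the control CPA is a
length-weighted mean of ~22 half-normal |Z| terms and is therefore
slightly right-skewed (skew ≈ 0.24 under the default generator).  The
normal fit consequently under-covers the upper tail: the empirical flag
rate on held-out synthetic controls runs near 1.3–1.5% rather than the
nominal 1%.  A Lilliefors check at a realistic control-group size (n = 60)
cannot detect skew of this size, which is presumably why the normality
assumption appears adequate at study scale.

## Histological classification

Profiles are discretized per bin into {−1, 0, +1} (loss / copy neutral /
gain) — from segment calls for sequencing profiles, or with a symmetric
±0.1 log2 threshold for array-style continuous segmental states.  Discrete
states deliberately discard amplitude, side-lining tumor fraction as a
variance source (at the cost of down-weighting focal amplifications).

The classifier is a multinomial (softmax) logistic regression with ridge
penalty over the usable bins, trained on a class-balanced subsample
(smallest-class size per class).  The regularization strength is chosen by
stratified 5-fold cross-validation over a log-spaced grid 10⁻³–10³,
selecting on pooled one-vs-all mean AUC with ties toward the stronger
penalty.  Evaluation is leave-one-out cross-validation (LOOV): each fold
re-runs strength selection and fitting without the held-out sample, whose
pooled class probabilities feed per-class one-vs-all ROC AUCs, their mean
(mAUC), and argmax accuracy.  SCLC-vs-NSCLC discrimination uses p(SCLC)
against the pooled LUAD+LUSC class.

Because the feature dimension (thousands of bins) far exceeds the sample
count, ridge fits use an exact reduction: with an L2 penalty the optimal
weight vector lies in the span of the training rows, so the model is
fitted in the eigenbasis of the training Gram matrix and coefficients are
mapped back.  This is the identical convex optimum (verified against
direct fits in the tests), not an approximation, and makes LOOV with
nested strength selection affordable.  Random forest, SVM, lasso and
elastic-net families are available as a comparison harness; ridge logistic
is the first-class deliverable.

Samples with no detectable aberration (all-zero feature rows) still
receive a prediction — the model falls back on its intercepts, i.e. the
prior-dominant class — but are flagged so they can be dismissed.

## Concordance analytics

Paired profiles are compared after a centred 100-bin moving-average
smoothing (window shrunk at chromosome edges, never crossing a
chromosome): Pearson correlation over common usable bins, and a
total-least-squares slope (first principal axis of the centred scatter;
slope > 1 means the second profile's amplitudes, hence tumor fraction,
exceed the first's).  Group summaries weight paired statistics by
w = 1/(1 + days)², down-weighting pairs whose biopsies are separated by
long intervals; the quadratic form mirrors quadratic dot-size scaling, and
the decreasing direction treats interval time as a confounder.

Cohort groups are summarized as aberration-frequency waves (% of samples
called gain / loss per bin) and clustered by complete linkage on the
Pearson distance d = (1 − r)/2 between signed waves (%gain − %loss).
Constant waves have undefined correlation and are dropped with a warning.

## Insert-size enrichment

Tumor-derived cfDNA fragments run shorter than the ~167 bp mononucleosomal
peak of healthy cfDNA.  Filtering paired-end reads to insert sizes in
[90, 135] bp (both ends inclusive) enriches the tumor fraction to

    f' = f·p_t / (f·p_t + (1 − f)·p_n)

where p_t, p_n are the per-origin filter pass rates.  Three arms are
derived per sample: raw reads, filtered reads, and a random downsample
matched to the filtered read count — the negative control separating
enrichment from count-loss noise.  Read counts are binned, scaled by
library size and compared against expected proportions (log2
observed/expected); amplitude deltas (|segment mean| per arm) are
summarized with a normal 95% CI over the segments called aberrant:
near-neutral segments would fold count noise into |mean| and bias every
arm upward at shallow depth.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:

- **Genome** — the 22 human autosomes scaled by a factor (default 0.1,
  ~2,900 usable 100 kb bins) with a masked centromeric band per
  chromosome; sex chromosomes are excluded to avoid constitutional-copy
  modelling.  Scale 1.0 restores full autosome lengths.
- **Noise** — per-bin standard deviations drawn once per cohort from
  U(0.04, 0.12), the range typical of 100 kb bins at 0.1–0.5× coverage;
  controls and cases share them, and panel weights derive from them.
- **Reference panel** — 200 controls by default, the same order as the
  reference sets such pipelines are normalized against (hundreds).
- **Subtype fingerprints** — arm-level recurrent events with penetrances:
  1p/9p gained in SCLC but lost in the NSCLC subtypes, 3p loss most
  penetrant in SCLC, 5p gain shared, 3q gain marking LUSC, 19p loss
  marking LUAD, chromosome 22 loss enriched in SCLC.  The penetrance
  values are qualitative defaults chosen to reproduce the direction of
  these contrasts, not measured frequencies.  Gains are simulated at 3
  copies and losses at 1 by default; amplifications are available per
  event.
- **Training table** — array-style segmental continuous states: the
  noiseless expected ratio per truth segment plus one Gaussian
  perturbation per segment (array data is segmental, so noise is shared
  within a segment), with tissue-like tumor fractions U(0.3, 0.9).
- **Fragments** — a two-component Gaussian insert-size mixture, normal
  (167, 12) and tumor (145, 25) bp, integer-rounded; reads land in bins
  proportionally to local DNA content and carry their true origin label
  for closed-form checks.

Not emulated: GC and mappability bias, the within-sample normalization
that produces the input ratios, sequence-level reads, the ~10 bp
periodicity of cfDNA fragment sizes, subclonal heterogeneity, and
FFPE-specific noise.  Passing tests therefore demonstrate correctness of
the statistics under the stated model, not robustness to real-data
artifacts upstream of the bin-ratio representation.

## Problem sizes of the reference experiments

The experiments in `cfcna.benchmarks` (run by `scripts/acceptance.py` and
the acceptance tests) use: 1,000 random small instances for the Z-score
formula check; 500 + 10,000 controls on a 0.022-scale genome (~600 usable
bins) for the FDR calibration; 15 paired replicates across tumor fractions
{0, 0.05, 0.1, 0.2, 0.4, 0.8} at scale 0.05 for CPA monotonicity; 200
simulations per arm for step recovery; the 68-per-class balanced cohort
(penetrance 0.9, f ~ U(0.3, 0.8)) at scale 0.1 for classifier LOOV; a
weakly separable 20-per-class cohort for the leakage check; and 10⁵ reads
for the enrichment closed form.

## Known limitations

- CPA depends on segmentation granularity (division by n); comparisons
  are only meaningful under one segmentation policy.
- The normal fit of control CPA scores under-covers its right tail (see
  above); the 1% FDR is nominal, empirically ~1.3–1.5% under this
  generator.
- The classifier harness's non-ridge families use naive LOOV loops and
  are intended for small cohorts only.
- Real-BAM ingestion is out of scope; the fragmentomics stage consumes
  pre-binned read records.
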