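# cfcna

Copy-number analysis of cell-free DNA (cfDNA) from shallow whole-genome
sequencing, for molecular-pathology and liquid-biopsy method developers.
Starting from bin-wise (100 kb) log2 coverage ratios, the package

- segments profiles into stretches of equal copy number
  (circular-binary-segmentation-style with a permutation test),
- standardizes each segment against a healthy reference panel
  (segmental Z-scores, |Z| ≥ 3 aberration calls),
- condenses a profile into the **CPA** tumor-burden score and calls
  genomic abnormality at a control-calibrated false-discovery-rate cutoff,
- classifies histology (LUAD / LUSC / SCLC) from discretized per-bin
  states with a ridge-penalized multinomial logistic regression under
  leave-one-out cross-validation,
- quantifies paired solid/liquid profile concordance (smoothing, Pearson
  r, total-least-squares slope, aberration-frequency waves, complete-
  linkage clustering), and
- performs in-silico tumor enrichment by insert-size filtering
  (90–135 bp) with a matched random-downsampling negative control.

A fully synthetic cfDNA cohort generator (subtype-fingerprinted cases,
control panels, array-style training tables, fragment-size-annotated
reads) makes every stage testable without external data.

## The core statistics

A segment spanning bins n..m of a case profile R is scored against a panel
of p control profiles r₁..r_p:

    Z_segment(n→m) = ( μ_w(R_n..R_m) − mean_p[ μ_w(r_{p,n}..r_{p,m}) ] )
                     / sd_p[ μ_w(r_{p,n}..r_{p,m}) ]

where μ_w is the mean weighted by reciprocal normal variability per bin.
Gains are called at Z ≥ +3, losses at Z ≤ −3.  A profile of n segments
with lengths l_i (per 100 Mb) gets the copy number profile abnormality
score

    CPA = Σ_i |Z_i| · l_i / n ,

and a sample is abnormal at FDR α when its CPA exceeds the (1 − α)
quantile of a normal distribution fitted to control CPA scores.  The
expected log2 ratio of a region at k tumor copies and tumor fraction f is
log2((2(1−f) + k·f)/2), which ties amplitudes to tumor fraction and
underlies both the simulator and the insert-size enrichment closed form
f′ = f·p_t / (f·p_t + (1−f)·p_n).

See `docs/methods.md` for the full model, design choices and limitations.

## Worked example

Calibrate an abnormality cutoff on 60 synthetic healthy controls, then
score a simulated SCLC liquid biopsy at tumor fraction 0.35:

```python
from cfcna import (CohortConfig, SyntheticCohort, SegmentationParams,
                   segment_profile, annotate_segments, cpa_score,
                   calibrate_cutoff, classify_abnormal)

cohort = SyntheticCohort(CohortConfig(seed=11, scale=0.05))
params = SegmentationParams(seed=11)

controls = []
for i in range(60):
    prof = cohort.control_profile(f"control_{i}")
    segs = annotate_segments(segment_profile(prof, cohort.grid, params),
                             prof, cohort.panel, cohort.grid)
    controls.append(cpa_score(segs))
calib = calibrate_cutoff(controls, fdr=0.01, lilliefors_seed=11)
print(calib.summary())

prof, _ = cohort.case("SCLC", tumor_fraction=0.35, sample_id="patient_SCLC")
segs = annotate_segments(segment_profile(prof, cohort.grid, params),
                         prof, cohort.panel, cohort.grid)
res = classify_abnormal([cpa_score(segs)], calib)[0]
print(f"CPA = {res.cpa:.3f} (cutoff {calib.cutoff:.3f}) "
      f"-> abnormal = {res.abnormal}")
```

prints

```
Abnormality cutoff calibration
------------------------------
modality        : liquid
controls        : 60
normal fit      : mu = 0.0493, sigma = 0.0111
FDR             : 0.01
cutoff          : 0.0753
Lilliefors p    : 0.030
CPA = 0.168 (cutoff 0.075) -> abnormal = True
```

The controls' CPA scores centre at 0.049; the 1%-FDR cutoff lands at the
0.99 normal quantile (0.075).  The SCLC case's aberrant segments (1p/9p/5p
gains, 3p losses at tumor fraction 0.35) lift its CPA to 0.168, roughly
11 control standard deviations above the control mean, so it is flagged
abnormal.  On the reduced simulation genome CPA values are smaller than
on a full genome (segment lengths enter in units of 100 Mb); the control
distribution and cutoff shrink with them.

The same stages are scriptable from the shell (`cfcna simulate`,
`cfcna segment`, `cfcna score`, `cfcna calibrate`, `cfcna classify ...`,
`cfcna fragment`, `cfcna concordance`, `cfcna run-all`).

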