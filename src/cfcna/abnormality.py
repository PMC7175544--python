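"""Segmental Z-scores, aberration calls, the CPA tumor-burden score, and
control-based abnormality calibration.

The Z-score of a segment compares the case's weighted mean ratio over the
segment's bins with the distribution of the same weighted mean across the
control panel::

    Z = (mu_w(case) - mean_p(mu_w(control_p))) / sd_p(mu_w(control_p))

with per-bin weights shared between case and controls (reciprocal normal
variability).  A segment is called a gain at Z >= +3, a loss at Z <= -3,
and neutral otherwise.

The copy number profile abnormality (CPA) score condenses a whole profile
into one tumor-burden number::

    CPA = sum_i |Z_i| * l_i / n        (l_i in units of 100 Mb)

An abnormality cutoff is calibrated on control samples by fitting a normal
distribution to their CPA scores and taking the (1 - fdr) quantile; samples
strictly above the cutoff are flagged abnormal at that false discovery
rate.  Normality of the control scores is checked with a Monte-Carlo
Lilliefors test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .genome import UndeterminableSegmentError, weighted_mean

__all__ = [
    "segment_zscore",
    "call_segment",
    "annotate_segments",
    "cpa_score",
    "CpaResult",
    "CutoffCalibration",
    "calibrate_cutoff",
    "lilliefors_normality",
    "classify_abnormal",
]

Z_CALL_THRESHOLD = 3.0


def segment_zscore(profile, panel, grid, segment):
    """Segmental Z-score of ``segment`` for ``profile`` against the panel.

    Raises :class:`UndeterminableSegmentError` when the control means have
    zero spread over the segment (such segments are excluded from the CPA).
    """
    sl = segment.bin_slice()
    case_mu = weighted_mean(profile.ratios[sl], grid.weights[sl])
    w = grid.weights[sl]
    keep = w > 0
    sub = panel.control_ratios[:, sl][:, keep]
    wk = w[keep]
    ctrl_mu = sub @ wk / wk.sum()
    sd = float(ctrl_mu.std(ddof=0))
    if sd == 0.0 or not np.isfinite(sd):
        raise UndeterminableSegmentError("zero control spread over segment")
    return (case_mu - float(ctrl_mu.mean())) / sd


def call_segment(z):
    """Aberration call from a segmental Z-score: |Z| >= 3 is aberrant."""
    if not np.isfinite(z):
        raise ValueError("non-finite Z-score")
    if z >= Z_CALL_THRESHOLD:
        return "gain"
    if z <= -Z_CALL_THRESHOLD:
        return "loss"
    return "neutral"


def annotate_segments(segset, profile, panel, grid):
    """Fill z_score and call on every segment of ``segset`` (in place copy).

    Segments with zero panel spread are marked non-determinable and keep an
    unset call; they are dropped from the CPA numerator and denominator.
    """
    out = []
    for seg in segset.segments:
        try:
            z = segment_zscore(profile, panel, grid, seg)
            out.append(
                replace(seg, z_score=z, call=call_segment(z), determinable=True)
            )
        except UndeterminableSegmentError:
            out.append(replace(seg, z_score=float("nan"), call="unset",
                               determinable=False))
    return replace_segments(segset, out)


def replace_segments(segset, segments):
    from .genome import SegmentSet

    return SegmentSet(segset.sample_id, segments, modality=segset.modality)


@dataclass
class CpaResult:
    """CPA score of one sample; ``abnormal`` stays None until a calibration
    is applied."""

    sample_id: str
    cpa: float
    n_segments: int
    modality: str = "liquid"
    abnormal: bool | None = None


def cpa_score(segset):
    """CPA = Σ |Z_i| · l_i / n over determinable segments, l_i per 100 Mb."""
    segs = [s for s in segset.segments if s.determinable]
    if not segs:
        raise UndeterminableSegmentError("no determinable segment; CPA undefined")
    z = np.array([abs(s.z_score) for s in segs])
    if np.any(~np.isfinite(z)):
        raise ValueError("annotate segments before scoring")
    l = np.array([s.length_bp for s in segs], dtype=float) / 1e8
    return CpaResult(
        sample_id=segset.sample_id,
        cpa=float(np.sum(z * l) / len(segs)),
        n_segments=len(segs),
        modality=segset.modality,
    )


@dataclass
class CutoffCalibration:
    """Normal fit of control CPA scores and the derived abnormality cutoff.

    cutoff = mu + Phi^-1(1 - fdr) * sigma.  ``lilliefors_p`` records the
    Monte-Carlo normality check of the control scores.
    """

    mu: float
    sigma: float
    fdr: float
    cutoff: float
    lilliefors_p: float
    modality: str = "liquid"
    n_controls: int = 0

    def summary(self):
        lines = [
            "Abnormality cutoff calibration",
            "------------------------------",
            f"modality        : {self.modality}",
            f"controls        : {self.n_controls}",
            f"normal fit      : mu = {self.mu:.4f}, sigma = {self.sigma:.4f}",
            f"FDR             : {self.fdr:g}",
            f"cutoff          : {self.cutoff:.4f}",
            f"Lilliefors p    : {self.lilliefors_p:.3f}",
        ]
        return "\n".join(lines)


def calibrate_cutoff(control_cpas, fdr=0.01, modality="liquid",
                     lilliefors_seed=0, n_mc=2000):
    """Fit a normal to control CPA scores and place the cutoff at the
    (1 - fdr) quantile of the fitted distribution.

    The fit uses the sample standard deviation (ddof=1).  Fewer than ~20
    controls give an unstable calibration; a warning is emitted.
    """
    x = np.asarray([c.cpa if isinstance(c, CpaResult) else c
                    for c in control_cpas], dtype=float)
    if x.size < 20:
        warnings.warn("fewer than 20 control CPA values; calibration unstable")
    if not 0 < fdr < 1:
        raise ValueError("fdr must lie in (0, 1)")
    mu = float(x.mean())
    sigma = float(x.std(ddof=1)) if x.size > 1 else 0.0
    if sigma <= 1e-12 * max(1.0, abs(mu)):  # constant input up to roundoff
        sigma = 0.0
        warnings.warn("zero spread in control CPA scores; cutoff degenerates to mu")
        cutoff = mu
        lp = float("nan")
    else:
        cutoff = mu + stats.norm.ppf(1 - fdr) * sigma
        lp = lilliefors_normality(x, n_mc=n_mc, seed=lilliefors_seed)
    return CutoffCalibration(mu=mu, sigma=sigma, fdr=fdr, cutoff=cutoff,
                             lilliefors_p=lp, modality=modality,
                             n_controls=int(x.size))


def lilliefors_normality(values, n_mc=10_000, seed=0):
    """Lilliefors test of composite normality, Monte-Carlo p-value.

    The KS statistic is computed against the normal fitted to the data;
    the null distribution is obtained by refitting on standard-normal
    samples of the same size (parameters re-estimated per replicate).
    p = (1 + #{D* >= D}) / (1 + n_mc).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant input; normality undefined")

    def ks_stat(sorted_sample):
        s = sorted_sample.std(ddof=1, axis=-1, keepdims=True)
        m = sorted_sample.mean(axis=-1, keepdims=True)
        cdf = stats.norm.cdf((sorted_sample - m) / s)
        i = np.arange(1, n + 1)
        d_plus = (i / n - cdf).max(axis=-1)
        d_minus = (cdf - (i - 1) / n).max(axis=-1)
        return np.maximum(d_plus, d_minus)

    d_obs = float(ks_stat(x))
    rng = np.random.default_rng(seed)
    null = rng.standard_normal((int(n_mc), n))
    null.sort(axis=1)
    d_null = ks_stat(null)
    return float((1 + np.count_nonzero(d_null >= d_obs)) / (1 + n_mc))


def classify_abnormal(cpa_results, calibration):
    """Flag samples whose CPA strictly exceeds the calibrated cutoff."""
    out = []
    for r in cpa_results:
        if r.modality != calibration.modality:
            warnings.warn(
                f"sample {r.sample_id}: modality {r.modality!r} does not match "
                f"calibration {calibration.modality!r}"
            )
        out.append(replace(r, abnormal=bool(r.cpa > calibration.cutoff)))
    return out
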