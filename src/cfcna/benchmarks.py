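"""Reference experiments exercising the pipeline end to end.

Each function runs one self-contained study on synthetic data — seeded,
deterministic, sized to run on a single CPU in minutes — and returns the
measured quantities as a plain dict.  The test suite asserts properties of
these measurements; ``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

import numpy as np

from .abnormality import annotate_segments, calibrate_cutoff, cpa_score
from .classification import FeatureMatrix, discretize_features, loov_evaluate, binary_grouping
from .fragmentomics import (amplitude_shift, enriched_tumor_fraction,
                            filter_by_insert_size, run_pipeline_triple,
                            size_filter_pass_rates)
from .genome import (BinGrid, CopyNumberProfile, ReferencePanel, Segment,
                     SegmentSet)
from .segmentation import SegmentationParams, segment_profile
from .simulate import (CohortConfig, FragmentModel, SyntheticCohort,
                       simulate_fragments)

__all__ = [
    "zscore_formula_agreement",
    "cpa_worked_example",
    "fdr_calibration_experiment",
    "cpa_monotonicity_experiment",
    "segmentation_recovery_experiment",
    "classifier_experiment",
    "enrichment_experiment",
    "leakage_experiment",
]


def _seeds(seed, n):
    return [int(s.generate_state(1)[0] % (1 << 31))
            for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# segmental Z-score against direct formula evaluation
# ---------------------------------------------------------------------------

def zscore_formula_agreement(seed=0, n_instances=1000):
    """Max |difference| between the pipeline Z-score and a direct
    evaluation of its defining formula on random small instances
    (<= 10 bins, <= 8 controls); differences are scaled by max(1, |Z|)."""
    from .abnormality import segment_zscore

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(1, 11))
        p = int(rng.integers(2, 9))
        grid = BinGrid.from_chromosomes([("1", n * 100_000)],
                                        bin_width=100_000)
        grid = grid.with_weights(rng.uniform(0.5, 5, n))
        ctrl = rng.normal(0, 1, (p, n))
        case = rng.normal(0, 1, n)
        w = grid.weights
        ctrl_means = np.array([np.sum(w * ctrl[k]) / np.sum(w)
                               for k in range(p)])
        sd = ctrl_means.std(ddof=0)
        if sd == 0:
            continue
        direct = (np.sum(w * case) / np.sum(w) - ctrl_means.mean()) / sd
        seg = Segment("1", 0, n - 1, 0.0, n * 100_000, n)
        z = segment_zscore(CopyNumberProfile("c", grid, case),
                           ReferencePanel(grid, ctrl), grid, seg)
        worst = max(worst, abs(z - direct) / max(1.0, abs(direct)))
    return {"max_scaled_error": worst, "n_instances": n_instances}


def cpa_worked_example():
    """CPA of the hand-computed two-segment instance:
    (|Z|=4, 50 Mb) and (|Z|=0.5, 250 Mb), n=2 -> 1.625."""
    grid = BinGrid.from_chromosomes([("1", 500_000)], bin_width=100_000)
    segs = SegmentSet("worked", [
        Segment("1", 0, 2, 0.3, 50_000_000, 3, z_score=4.0, call="gain"),
        Segment("1", 3, 4, -0.05, 250_000_000, 2, z_score=-0.5,
                call="neutral"),
    ])
    return {"cpa": cpa_score(segs).cpa, "expected": 1.625}


# ---------------------------------------------------------------------------
# abnormality-calling FDR calibration
# ---------------------------------------------------------------------------

def _control_cpa_stream(cohort, params, n, offset=0):
    for i in range(n):
        prof = cohort.control_profile(f"ctrl_{offset + i}")
        segset = segment_profile(prof, cohort.grid, params)
        segset = annotate_segments(segset, prof, cohort.panel, cohort.grid)
        yield cpa_score(segset).cpa


def fdr_calibration_experiment(seed=0, n_fit=500, n_heldout=10_000,
                               scale=0.022, fdr=0.01):
    """Calibrate the abnormality cutoff on ``n_fit`` synthetic controls and
    measure the empirical flag rate on held-out controls.

    Runs on a scaled-down genome (~600 usable bins) so the ~10,500
    segmentations finish in minutes."""
    cohort = SyntheticCohort(CohortConfig(seed=seed, scale=scale))
    params = SegmentationParams(seed=seed)
    fit = np.fromiter(_control_cpa_stream(cohort, params, n_fit), float)
    calib = calibrate_cutoff(fit, fdr=fdr, lilliefors_seed=seed, n_mc=2000)
    held = np.fromiter(
        _control_cpa_stream(cohort, params, n_heldout, offset=n_fit), float)
    flagged = int((held > calib.cutoff).sum())
    return {
        "flag_rate_pct": 100.0 * flagged / n_heldout,
        "n_flagged": flagged,
        "n_heldout": n_heldout,
        "cutoff": calib.cutoff,
        "lilliefors_p": calib.lilliefors_p,
    }


# ---------------------------------------------------------------------------
# CPA monotonicity in tumor fraction
# ---------------------------------------------------------------------------

def cpa_monotonicity_experiment(seed=0, n_reps=15, scale=0.05,
                                f_grid=(0.0, 0.05, 0.1, 0.2, 0.4, 0.8)):
    """Median CPA across replicates at each tumor fraction, with paired
    noise (one noise vector per replicate, reused across the f grid) and a
    fixed fingerprint (every SCLC event realized)."""
    cohort = SyntheticCohort(CohortConfig(seed=seed, scale=scale))
    params = SegmentationParams(seed=seed)
    fp = cohort.fingerprints["SCLC"]
    rng = np.random.default_rng(seed + 1)
    cpas = np.zeros((n_reps, len(f_grid)))
    for rep in range(n_reps):
        noise = rng.standard_normal(cohort.grid.n_bins)
        for k, f in enumerate(f_grid):
            from .simulate import simulate_case

            prof, _ = simulate_case(cohort.grid, fp, f, cohort.bin_sds,
                                    np.random.default_rng(seed),
                                    sample_id=f"f{f}", penetrance=1.0,
                                    noise=noise)
            segset = segment_profile(prof, cohort.grid, params)
            segset = annotate_segments(segset, prof, cohort.panel, cohort.grid)
            cpas[rep, k] = cpa_score(segset).cpa
    medians = np.median(cpas, axis=0)
    return {
        "f_grid": list(f_grid),
        "median_cpa": [float(m) for m in medians],
        "strictly_increasing": bool(np.all(np.diff(medians) > 0)),
    }


# ---------------------------------------------------------------------------
# segmentation recovery
# ---------------------------------------------------------------------------

def segmentation_recovery_experiment(seed=0, n_sims=200, n_bins=100,
                                     step_height_sd=6.0):
    """Breakpoint recovery of a single step and the false-split rate on
    pure noise, on one 100-bin chromosome."""
    grid = BinGrid.from_chromosomes([("1", n_bins * 100_000)],
                                    bin_width=100_000)
    rng = np.random.default_rng(seed)
    step_hits = 0
    for k in range(n_sims):
        x = rng.normal(0, 1, n_bins)
        x[n_bins // 2:] += step_height_sd
        segs = segment_profile(CopyNumberProfile("s", grid, x), grid,
                               SegmentationParams(seed=seed + k))
        breaks = [s.end_bin + 1 for s in segs.segments[:-1]]
        step_hits += any(abs(b - n_bins // 2) <= 2 for b in breaks)
    noise_single = 0
    for k in range(n_sims):
        x = rng.normal(0, 1, n_bins)
        segs = segment_profile(CopyNumberProfile("s", grid, x), grid,
                               SegmentationParams(seed=seed + n_sims + k))
        noise_single += segs.n_segments == 1
    return {
        "step_recovery_pct": 100.0 * step_hits / n_sims,
        "noise_single_segment_pct": 100.0 * noise_single / n_sims,
        "n_sims": n_sims,
    }


# ---------------------------------------------------------------------------
# classifier evaluation
# ---------------------------------------------------------------------------

def _balanced_cohort_features(seed, n_per_class=68, penetrance=0.9,
                              tumor_fraction_range=(0.3, 0.8), scale=0.1):
    cohort = SyntheticCohort(CohortConfig(seed=seed, scale=scale))
    states, labels, ids = cohort.training_table(
        n_per_class=n_per_class, penetrance=penetrance,
        tumor_fraction_range=tumor_fraction_range)
    return cohort, discretize_features(states, cohort.grid, labels=labels,
                                       sample_ids=ids)


def classifier_experiment(seed=0, n_per_class=68):
    """LOOV of the ridge classifier on the default balanced cohort
    (penetrance 0.9, tumor fractions 0.3-0.8), plus a permuted-label run."""
    cohort, fm = _balanced_cohort_features(seed, n_per_class=n_per_class)
    report = loov_evaluate(fm, seed=seed)
    grouped = binary_grouping(report.labels, report.proba, report.classes)
    rng = np.random.default_rng(seed + 1)
    fm_perm = FeatureMatrix(fm.X, rng.permutation(fm.labels),
                            fm.sample_ids, fm.bin_indices)
    perm = loov_evaluate(fm_perm, seed=seed)
    return {
        "mauc": report.mauc,
        "accuracy": report.accuracy,
        "sclc_vs_nsclc_auc": grouped["auc"],
        "permuted_mauc": perm.mauc,
        "n_samples": fm.n_samples,
    }


def leakage_experiment(seed=0, n_per_class=20):
    """LOOV with a label-revealing feature present only at prediction time
    for the held-out sample (training rows keep zeros there).

    Uses a weakly separable cohort (penetrance 0.5, low tumor fractions)
    so an actual leak would have headroom to raise the mAUC; a fully
    injected run (revealing values in training rows too) provides the
    positive control."""
    _, fm = _balanced_cohort_features(seed, n_per_class=n_per_class,
                                      penetrance=0.5,
                                      tumor_fraction_range=(0.08, 0.3),
                                      scale=0.05)
    classes = {c: k for k, c in enumerate(np.unique(fm.labels))}
    reveal = np.array([classes[c] - 1 for c in fm.labels], dtype=np.int8)
    X_zero = np.hstack([fm.X, np.zeros((fm.n_samples, 1), dtype=np.int8)])
    X_reveal = np.hstack([fm.X, reveal[:, None]])
    bins = np.arange(X_zero.shape[1])
    base = loov_evaluate(
        FeatureMatrix(X_zero, fm.labels, fm.sample_ids, bins), seed=seed)
    injected = loov_evaluate(
        FeatureMatrix(X_zero, fm.labels, fm.sample_ids, bins), seed=seed,
        holdout_X=X_reveal.astype(float))
    leaky = loov_evaluate(
        FeatureMatrix(X_reveal, fm.labels, fm.sample_ids, bins), seed=seed)
    return {
        "base_mauc": base.mauc,
        "holdout_injected_mauc": injected.mauc,
        "delta": injected.mauc - base.mauc,
        "train_injected_mauc": leaky.mauc,
    }


# ---------------------------------------------------------------------------
# insert-size enrichment
# ---------------------------------------------------------------------------

def enrichment_experiment(seed=0, n_reads=100_000, tumor_fraction=0.2):
    """Tumor-origin share after the 90-135 bp filter versus the closed
    form, and the matched-downsample negative control's amplitude deltas.

    Amplitude deltas are measured over the aberrant segments (the quantity
    of interest concerns called CNAs); neutral segments would fold count
    noise into |mean| and bias every arm upward at shallow depth."""
    from .simulate import _truth_segments, default_grid

    grid = default_grid(scale=0.01)
    rng = np.random.default_rng(seed)
    model = FragmentModel()
    copy_state = np.full(grid.n_bins, 2)
    expect = np.zeros(grid.n_bins)
    events = (("2", 3, 1.0), ("5", 1, -1.0), ("7", 3, 1.0), ("9", 1, -1.0),
              ("12", 3, 1.0), ("14", 1, -1.0), ("17", 3, 1.0), ("19", 1, -1.0))
    for chrom, copies, direction in events:
        idx = grid.chrom_bins(chrom)
        copy_state[idx] = copies
        expect[idx] = direction
    reads = simulate_fragments(n_reads, tumor_fraction, copy_state, grid,
                               model, rng)
    filtered = filter_by_insert_size(reads)
    share = float((filtered["origin"] == "tumor").mean())
    pass_t, pass_n = size_filter_pass_rates(model)
    f_prime = enriched_tumor_fraction(tumor_fraction, pass_t, pass_n)
    se = float(np.sqrt(f_prime * (1 - f_prime) / len(filtered)))
    triple = run_pipeline_triple(reads, grid, seed=seed)
    truth = _truth_segments(grid, expect, "case")
    aberrant = [s for s in truth.segments if s.mean_ratio != 0]
    _, summary = amplitude_shift(triple, aberrant)
    return {
        "measured_tumor_share": share,
        "predicted_tumor_share": f_prime,
        "share_abs_error": abs(share - f_prime),
        "share_se": se,
        "n_filtered": len(filtered),
        "filtered_delta_mean": summary["delta_filtered"]["mean"],
        "downsample_delta_mean": summary["delta_downsampled"]["mean"],
        "downsample_delta_ci": (summary["delta_downsampled"]["ci_low"],
                                summary["delta_downsampled"]["ci_high"]),
    }
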