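"""End-to-end orchestration on a synthetic cohort.

Stage order mirrors the analysis: profiling -> segmentation -> aberration
calling -> CPA -> abnormality calibration -> classification ->
concordance summaries.  Every stage writes its table to the output
directory; a manifest records seeds, parameters and stage outputs so a
re-run of the same config is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .abnormality import annotate_segments, calibrate_cutoff, classify_abnormal, cpa_score
from .classification import (balanced_subsample, discretize_features,
                             loov_evaluate, predict, train_model)
from .concordance import aberration_frequency_waves, cluster_groups
from .segmentation import SegmentationParams, segment_profile
from .simulate import CohortConfig, SyntheticCohort

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated parameters of a full synthetic run."""

    seed: int = 0
    output_dir: str = "cfcna_run"
    n_controls_eval: int = 40
    n_cases_per_class: int = 10
    n_training_per_class: int = 30
    scale: float = 0.05
    alpha: float = 0.01
    n_permutations: int = 1000
    fdr: float = 0.01
    state_threshold: float = 0.1
    run_loov: bool = False
    cohort: CohortConfig = field(default=None)

    def __post_init__(self):
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        SegmentationParams(alpha=self.alpha,
                           n_permutations=self.n_permutations)
        if self.n_controls_eval < 20:
            raise ValueError("need at least 20 evaluation controls")
        if self.cohort is None:
            self.cohort = CohortConfig(seed=self.seed, scale=self.scale)


def _segment_and_score(profile, cohort, params):
    segset = segment_profile(profile, cohort.grid, params)
    segset = annotate_segments(segset, profile, cohort.panel, cohort.grid)
    return segset, cpa_score(segset)


def run_pipeline(config):
    """Run every stage on a freshly simulated cohort; returns the output
    directory path."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = SyntheticCohort(config.cohort)
    params = SegmentationParams(alpha=config.alpha,
                                n_permutations=config.n_permutations,
                                seed=config.seed)
    io.write_grid(cohort.grid, out / "grid.tsv")

    # --- controls: CPA distribution and abnormality cutoff
    control_cpas = []
    for i in range(config.n_controls_eval):
        prof = cohort.control_profile(f"control_{i}")
        _, res = _segment_and_score(prof, cohort, params)
        control_cpas.append(res)
    calib = calibrate_cutoff(control_cpas, fdr=config.fdr,
                             lilliefors_seed=config.seed)

    # --- cases: segmentation, calls, CPA, abnormality
    case_results, case_segsets, labels = [], [], []
    by_class = {}
    for label in sorted(cohort.fingerprints):
        for i in range(config.n_cases_per_class):
            prof, _ = cohort.case(label, sample_id=f"{label}_{i}")
            segset, res = _segment_and_score(prof, cohort, params)
            io.write_segments(segset, cohort.grid,
                              out / f"segments_{prof.sample_id}.tsv",
                              annotated=True)
            case_results.append(res)
            case_segsets.append(segset)
            labels.append(label)
            by_class.setdefault(label, []).append(segset)
    case_results = classify_abnormal(case_results, calib)
    io.write_cpa_report(case_results, calib, out / "cpa_report.tsv")

    # --- classifier trained on the array-style table, applied to cases
    states, train_labels, _ = cohort.training_table(
        n_per_class=config.n_training_per_class)
    fm_train = discretize_features(states, cohort.grid,
                                   threshold=config.state_threshold,
                                   labels=train_labels)
    sel = balanced_subsample(fm_train.labels, seed=config.seed)
    from .classification import FeatureMatrix
    fm_bal = FeatureMatrix(fm_train.X[sel], fm_train.labels[sel],
                           [fm_train.sample_ids[i] for i in sel],
                           fm_train.bin_indices)
    io.write_feature_matrix(fm_bal, str(out / "training"))
    model = train_model(fm_bal, seed=config.seed)
    report = None
    if config.run_loov:
        report = loov_evaluate(fm_bal, seed=config.seed)
        (out / "loov_report.txt").write_text(report.summary() + "\n")
    fm_cases = discretize_features(case_segsets, cohort.grid,
                                   labels=np.array(labels))
    preds = predict(model, fm_cases)
    preds.to_csv(out / "predictions.tsv", sep="\t", index=False)

    # --- concordance: frequency waves and group clustering
    waves = aberration_frequency_waves(by_class, cohort.grid)
    link, names = cluster_groups(waves)
    np.savetxt(out / "cluster_linkage.tsv", link, delimiter="\t",
               header="\t".join(names), comments="# ")

    manifest = {
        "config": {k: v for k, v in asdict(config).items() if k != "cohort"},
        "cohort": asdict(config.cohort),
        "cutoff": calib.cutoff,
        "lilliefors_p": calib.lilliefors_p,
        "n_abnormal": int(sum(r.abnormal for r in case_results)),
        "classifier_C": model.C,
        "loov_mauc": None if report is None else report.mauc,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str) + "\n")
    io.write_config({
        "seed": config.seed, "alpha": config.alpha, "fdr": config.fdr,
        "cutoff": f"{calib.cutoff:.6f}",
    }, out / "run.cfg")
    return out
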