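"""Histological classification from discretized copy-number features.

Profiles are reduced to per-bin discrete states {-1, 0, +1} (loss / copy
neutral / gain) — a representation that partly sidelines tumor fraction as
a source of variability — and fed to a multinomial logistic regression with
ridge penalty.  Evaluation follows leave-one-out cross-validation with
one-vs-all ROC analysis, summarized as the mean AUC (mAUC).

Ridge fits exploit an exact reduction: with an L2 penalty the optimal
weight vector lies in the span of the training rows, so the model is fitted
in the (at most n-dimensional) eigenbasis of the training Gram matrix and
coefficients are mapped back.  This is an identical optimum, not an
approximation, and makes LOOV over thousands of bins affordable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "FeatureMatrix",
    "TrainedModel",
    "EvalReport",
    "discretize_features",
    "balanced_subsample",
    "train_model",
    "loov_evaluate",
    "predict",
    "roc_curve_auc",
    "coefficient_report",
    "binary_grouping",
]

DEFAULT_C_GRID = tuple(np.logspace(-3, 3, 7))
DEFAULT_STATE_THRESHOLD = 0.1


@dataclass
class FeatureMatrix:
    """Samples x usable-bins matrix of discrete states with class labels."""

    X: np.ndarray
    labels: np.ndarray
    sample_ids: list
    bin_indices: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X)
        if not np.isin(self.X, (-1, 0, 1)).all():
            raise ValueError("feature states must be -1, 0 or +1")
        self.X = self.X.astype(np.int8)

    @property
    def n_samples(self):
        return self.X.shape[0]

    def flat_rows(self):
        """Samples without any detectable aberration (all-zero rows)."""
        return ~np.any(self.X != 0, axis=1)


def discretize_features(inputs, grid, threshold=DEFAULT_STATE_THRESHOLD,
                        labels=None, sample_ids=None):
    """Build a FeatureMatrix from called SegmentSets or continuous states.

    Two input shapes are accepted:

    * a list of call-annotated :class:`SegmentSet` — each usable bin takes
      its covering segment's call (gain -> +1, loss -> -1);
    * a 2-D array of per-bin continuous states (the array-style training
      table) — states >= +threshold become +1, <= -threshold become -1.

    Bins masked on the grid are dropped; a usable bin covered by no
    segment stays 0 (with a warning).
    """
    usable = np.flatnonzero(grid.usable)
    if isinstance(inputs, np.ndarray):
        states = np.zeros_like(inputs, dtype=np.int8)
        states[inputs >= threshold] = 1
        states[inputs <= -threshold] = -1
        X = states[:, usable]
        ids = sample_ids or [f"sample_{i}" for i in range(X.shape[0])]
    else:
        call_value = {"gain": 1, "loss": -1, "neutral": 0, "unset": 0}
        rows, ids = [], []
        for segset in inputs:
            row = np.zeros(grid.n_bins, dtype=np.int8)
            covered = np.zeros(grid.n_bins, dtype=bool)
            for seg in segset.segments:
                sl = seg.bin_slice()
                row[sl] = call_value[seg.call]
                covered[sl] = True
            if not covered[usable].all():
                warnings.warn(
                    f"{segset.sample_id}: {int((~covered[usable]).sum())} usable "
                    "bins covered by no segment; set to copy neutral"
                )
            rows.append(row[usable])
            ids.append(segset.sample_id)
        X = np.array(rows)
    lab = None if labels is None else np.asarray(labels)
    return FeatureMatrix(X=X, labels=lab, sample_ids=ids, bin_indices=usable)


def balanced_subsample(labels, seed=0):
    """Indices of a class-balanced subset: smallest-class size per class,
    sampled without replacement, reproducible from the seed."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts == 0) or classes.size < 2:
        raise ValueError("need at least two non-empty classes")
    k = int(counts.min())
    rng = np.random.default_rng(seed)
    idx = np.concatenate([
        rng.choice(np.flatnonzero(labels == c), size=k, replace=False)
        for c in classes
    ])
    return np.sort(idx)


# ---------------------------------------------------------------------------
# ridge logistic via the exact Gram reduction
# ---------------------------------------------------------------------------

def _gram_basis(G, tol=1e-9):
    """Eigenbasis of a PSD Gram matrix; returns (U, s) with s the kept
    singular values (sqrt of eigenvalues above tol * max).  A rank-zero
    Gram (all-zero features) keeps one null direction so downstream fits
    reduce to intercept-only models."""
    w, U = eigh(G)
    w = np.clip(w, 0, None)
    keep = w > tol * max(w.max(), 1e-300)
    if not keep.any():
        return np.zeros((G.shape[0], 1)), np.array([1.0])
    return U[:, keep], np.sqrt(w[keep])


def _fit_logistic(Z, y, C, fast=False):
    # the fast profile serves inner-CV strength selection and per-fold LOOV
    # fits, where AUC-level results are insensitive to the last digits of
    # the optimum; convergence chatter at the iteration cap is expected on
    # unstructured (e.g. permuted-label) data and not informative
    max_iter, tol = (400, 1e-4) if fast else (5000, 1e-6)
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=max_iter, tol=tol)
    with warnings.catch_warnings():
        if fast:
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(Z, y)
    return clf


def _mauc(y_true, proba, classes):
    aucs = []
    for k, c in enumerate(classes):
        mask = (y_true == c).astype(int)
        if mask.min() == mask.max():
            continue
        aucs.append(roc_auc_score(mask, proba[:, k]))
    return float(np.mean(aucs)) if aucs else float("nan")


def _inner_select_c(Z, y, c_grid, inner_folds, seed):
    """Pick the ridge strength by pooled inner-CV mAUC; ties favour the
    stronger penalty (smaller C)."""
    classes = np.unique(y)
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(Z, y))
    best_c, best_score = None, -np.inf
    for C in sorted(c_grid):
        proba = np.zeros((len(y), classes.size))
        for tr, va in folds:
            clf = _fit_logistic(Z[tr], y[tr], C, fast=True)
            proba[va] = _proba_in_classes(clf, Z[va], classes)
        score = _mauc(y, proba, classes)
        if score > best_score + 1e-12:
            best_c, best_score = C, score
    return best_c


def _proba_in_classes(clf, Z, classes):
    p = clf.predict_proba(Z)
    out = np.zeros((Z.shape[0], classes.size))
    for j, c in enumerate(clf.classes_):
        out[:, np.flatnonzero(classes == c)[0]] = p[:, j]
    return out


@dataclass
class TrainedModel:
    """Fitted classifier with coefficients mapped back to bins.

    ``coef`` has one row per class over the feature bins (multinomial
    formulation); only linear families expose coefficients.
    """

    family: str
    classes: np.ndarray
    coef: np.ndarray | None
    intercept: np.ndarray | None
    C: float | None
    bin_indices: np.ndarray
    estimator: object = field(repr=False, default=None)
    seed: int = 0

    def coef_centered(self):
        """Coefficients with the per-feature class mean removed (the softmax
        parametrization is only identified up to a shared shift)."""
        return self.coef - self.coef.mean(axis=0)

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        if self.coef is not None:
            scores = X @ self.coef.T + self.intercept
            scores -= scores.max(axis=1, keepdims=True)
            e = np.exp(scores)
            return e / e.sum(axis=1, keepdims=True)
        return _proba_in_classes(self.estimator, X, self.classes)


def train_model(features, labels=None, family="ridge", C=None,
                c_grid=DEFAULT_C_GRID, inner_folds=5, seed=0):
    """Fit a classifier on a FeatureMatrix (or raw X with labels).

    For the first-class ridge family the regularization strength is chosen
    by inner stratified 5-fold CV over a log grid when not given.  Other
    families (lasso, elasticnet, rf, svm) form the comparison harness.
    """
    X, y = _unpack(features, labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes to train")
    bin_indices = getattr(features, "bin_indices", np.arange(X.shape[1]))
    if family == "ridge":
        G = X @ X.T
        U, s = _gram_basis(G)
        Z = U * s
        if C is None:
            C = _inner_select_c(Z, y, c_grid, inner_folds, seed)
        clf = _fit_logistic(Z, y, C)
        V = (X.T @ U) / s
        coef = clf.coef_ @ V.T
        if classes.size == 2:
            coef = np.vstack([-coef[0] / 2, coef[0] / 2])
            intercept = np.array([-clf.intercept_[0] / 2, clf.intercept_[0] / 2])
        else:
            intercept = clf.intercept_
        return TrainedModel(family, classes, coef, intercept, C,
                            bin_indices, estimator=None, seed=seed)
    est = _make_estimator(family, C, seed)
    est.fit(X, y)
    return TrainedModel(family, classes, None, None, C, bin_indices,
                        estimator=est, seed=seed)


def _make_estimator(family, C, seed):
    if family == "lasso":
        return LogisticRegression(penalty="l1", C=C or 1.0, solver="saga",
                                  max_iter=5000)
    if family == "elasticnet":
        return LogisticRegression(penalty="elasticnet", l1_ratio=0.5,
                                  C=C or 1.0, solver="saga", max_iter=5000)
    if family == "rf":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if family == "svm":
        return SVC(C=C or 1.0, probability=True, random_state=seed)
    raise ValueError(f"unknown family {family!r}")


def _unpack(features, labels):
    if isinstance(features, FeatureMatrix):
        X = features.X.astype(float)
        y = features.labels if labels is None else np.asarray(labels)
    else:
        X = np.asarray(features, dtype=float)
        y = np.asarray(labels)
    if y is None:
        raise ValueError("labels required")
    return X, y


@dataclass
class EvalReport:
    """Pooled LOOV evaluation: per-class one-vs-all AUCs, their mean, and
    per-sample predictions."""

    classes: np.ndarray
    per_class_auc: dict
    mauc: float
    accuracy: float
    proba: np.ndarray
    predicted: np.ndarray
    labels: np.ndarray
    sample_ids: list

    def summary(self):
        lines = [
            "Leave-one-out evaluation",
            "------------------------",
            f"samples        : {len(self.labels)}",
        ]
        for c in self.classes:
            lines.append(f"AUC {c:<10} : {self.per_class_auc[c]:.3f}")
        lines.append(f"mAUC           : {self.mauc:.3f}")
        lines.append(f"accuracy       : {self.accuracy:.3f}")
        return "\n".join(lines)


def loov_evaluate(features, labels=None, family="ridge", seed=0,
                  c_grid=DEFAULT_C_GRID, inner_folds=5, holdout_X=None):
    """Leave-one-out cross-validation with one-vs-all ROC analysis.

    For each sample, balancing aside, the model (including its inner-CV
    regularization choice) is built from the remaining samples only; the
    held-out sample's class probabilities are pooled and per-class AUCs,
    their mean (mAUC), and the argmax accuracy are reported.

    ``holdout_X`` optionally substitutes the feature row used *only at
    prediction time* for each held-out sample; training rows always come
    from ``features``.  (This is the hook for prediction-time-only feature
    perturbation experiments, e.g. leakage checks.)
    """
    X, y = _unpack(features, labels)
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 samples for LOOV")
    classes = np.unique(y)
    sample_ids = getattr(features, "sample_ids",
                         [f"sample_{i}" for i in range(n)])
    proba = np.zeros((n, classes.size))
    if family == "ridge":
        G = X @ X.T
        for i in range(n):
            tr = np.concatenate([np.arange(i), np.arange(i + 1, n)])
            U, s = _gram_basis(G[np.ix_(tr, tr)])
            Z = U * s
            C = _inner_select_c(Z, y[tr], c_grid, inner_folds, seed)
            clf = _fit_logistic(Z, y[tr], C, fast=True)
            x_test = X[i] if holdout_X is None else np.asarray(
                holdout_X, dtype=float)[i]
            k = X[tr] @ x_test
            z_test = (U.T @ k) / s
            proba[i] = _proba_in_classes(clf, z_test[None, :], classes)
    else:
        for i in range(n):
            tr = np.concatenate([np.arange(i), np.arange(i + 1, n)])
            est = _make_estimator(family, None, seed)
            est.fit(X[tr], y[tr])
            x_test = X[i] if holdout_X is None else np.asarray(
                holdout_X, dtype=float)[i]
            proba[i] = _proba_in_classes(est, x_test[None, :], classes)
    predicted = classes[np.argmax(proba, axis=1)]
    per_class = {}
    for k, c in enumerate(classes):
        per_class[c] = roc_curve_auc(proba[:, k], (y == c).astype(int))
    return EvalReport(
        classes=classes,
        per_class_auc=per_class,
        mauc=float(np.mean(list(per_class.values()))),
        accuracy=float(np.mean(predicted == y)),
        proba=proba,
        predicted=predicted,
        labels=y,
        sample_ids=list(sample_ids),
    )


def predict(model, features):
    """Class probabilities and labels for new samples.

    Flat rows (no detectable aberration anywhere) still receive a
    prediction but are flagged — with no signal the model falls back on
    its intercepts, i.e. the prior-dominant class.
    """
    if isinstance(features, FeatureMatrix):
        if not np.array_equal(features.bin_indices, model.bin_indices):
            raise ValueError("feature bins do not match the trained model")
        X = features.X.astype(float)
        ids = features.sample_ids
    else:
        X = np.asarray(features, dtype=float)
        ids = [f"sample_{i}" for i in range(X.shape[0])]
    if X.shape[1] != model.bin_indices.size:
        raise ValueError("feature bins do not match the trained model")
    proba = model.predict_proba(X)
    flat = ~np.any(X != 0, axis=1)
    return pd.DataFrame({
        "sample_id": ids,
        "predicted": model.classes[np.argmax(proba, axis=1)],
        "probability": proba.max(axis=1),
        "no_detectable_aberrations": flat,
        **{f"p_{c}": proba[:, k] for k, c in enumerate(model.classes)},
    })


def roc_curve_auc(scores, binary_labels):
    """One-vs-all ROC AUC (trapezoidal / midrank ties, i.e. Mann-Whitney)."""
    y = np.asarray(binary_labels)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def coefficient_report(model, grid, top_k=6):
    """Per-class loci ranked by |coefficient|, with arm-level aggregates.

    Returns ``(per_bin, per_arm)`` DataFrames; per_arm sums coefficients
    over each chromosome arm (the scale on which recurrent lung-cancer
    aberrations live).
    """
    if model.coef is None:
        raise ValueError("coefficient report requires a linear model")
    bins = model.bin_indices
    rows = []
    for k, c in enumerate(model.classes):
        coef = model.coef[k]
        order = np.argsort(-np.abs(coef))[:top_k]
        for rank, j in enumerate(order):
            b = bins[j]
            rows.append({
                "class": c, "rank": rank + 1, "bin": int(b),
                "chromosome": grid.chrom_names[grid.chrom_index[b]],
                "arm": str(grid.arms[b]), "start": int(grid.start[b]),
                "coefficient": float(coef[j]),
            })
    per_bin = pd.DataFrame(rows)
    arm_rows = []
    arms = grid.arms[bins]
    for k, c in enumerate(model.classes):
        df = pd.DataFrame({"arm": arms, "coef": model.coef[k]})
        agg = df.groupby("arm", sort=False)["coef"].sum().reset_index()
        agg["class"] = c
        arm_rows.append(agg)
    per_arm = (pd.concat(arm_rows, ignore_index=True)
               .sort_values("coef", key=np.abs, ascending=False,
                            ignore_index=True))
    return per_bin, per_arm


def binary_grouping(labels, proba, classes, positive="SCLC"):
    """Collapse three-class probabilities to SCLC vs NSCLC.

    The binary score is exactly p(SCLC); accuracy follows the three-class
    argmax rule collapsed to the two groups.
    """
    classes = np.asarray(classes)
    labels = np.asarray(labels)
    k = int(np.flatnonzero(classes == positive)[0])
    score = np.asarray(proba)[:, k]
    y = (labels == positive).astype(int)
    predicted_pos = classes[np.argmax(proba, axis=1)] == positive
    return {
        "auc": roc_curve_auc(score, y),
        "accuracy": float(np.mean(predicted_pos == (y == 1))),
        "score": score,
    }
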