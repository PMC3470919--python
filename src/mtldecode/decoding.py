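"""Final classification analyses: nested leave-one-trial-out decoding with
per-fold searchlight feature selection, and cross-condition generalization.

The decoding procedure mirrors the two-step scheme used for ROI decoding of
scene identity: on every outer fold one trial is held out, a searchlight
accuracy map is computed from the remaining trials only, the voxels of the
maximal-accuracy sphere (union on ties) are selected, a linear SVM (C=1) is
trained on those voxels, and the held-out trial is predicted. Accuracy is
the proportion of correct guesses over all k = n_trials folds.

Labels are participants' choices everywhere by default; stimulus labels are
available behind a flag for diagnostics. Trials at 50% morph level have no
stimulus-defined class, so stimulus labeling excludes them.

``DecodingModel`` is the statsmodels-style entry point: construct it from a
beta series (or a synthetic dataset) and call :meth:`DecodingModel.fit`
with an analysis id; it returns a :class:`DecodingResult` with fold
records, accuracy and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import svm
from .searchlight import (
    AccuracyMap,
    ClassifierSpec,
    DegenerateLabelsError,
    MaskGeometry,
    SearchlightSpec,
    _encode_labels,
    _inner_subset,
    searchlight_map,
    select_features,
)
from .volumes import ROIMask

__all__ = [
    "CrossValidationPlan",
    "DecodingResult",
    "DecodingModel",
    "nested_loocv_decode",
    "cross_condition_decode",
    "morph_generalization",
    "ANALYSES",
]

ANALYSES = ("100vs100", "50vs50", "train100_test50", "train50_test100", "morphgen")


class FoldDegeneracyError(ValueError):
    """A training fold lost one of the two classes."""


@dataclass(frozen=True)
class CrossValidationPlan:
    """Leave-one-trial-out plan: k equals the number of trials and each
    fold's feature selection sees only that fold's training trials."""

    n_trials: int
    feature_selection: str = "nested"  # or "all-trials" (leaky diagnostic)

    def __post_init__(self) -> None:
        if self.n_trials < 4:
            raise ValueError("need >= 4 trials for leave-one-trial-out")
        if self.feature_selection not in ("nested", "all-trials"):
            raise ValueError("feature_selection must be 'nested' or 'all-trials'")


@dataclass
class DecodingResult:
    """Fold-wise predictions and aggregate accuracy for one subject x ROI
    x analysis."""

    analysis: str
    roi: str
    folds: pd.DataFrame  # test_trial, true, predicted, correct, n_features
    accuracy: float
    n_folds: int
    class_counts: dict
    per_level: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError("accuracy must lie in [0, 1]")

    def summary(self) -> str:
        lines = [
            f"Decoding analysis: {self.analysis}   ROI: {self.roi}",
            f"Folds: {self.n_folds}   Accuracy: {self.accuracy:.4f}",
            "Class counts: "
            + ", ".join(f"{k}: {v}" for k, v in self.class_counts.items()),
        ]
        if "mean_n_features" in self.meta:
            lines.append(f"Mean selected voxels/fold: {self.meta['mean_n_features']:.1f}")
        if self.per_level is not None:
            lines.append("Per-level accuracy:")
            lines.append(self.per_level.to_string(index=False))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "analysis": self.analysis,
            "roi": self.roi,
            "accuracy": self.accuracy,
            "n_folds": self.n_folds,
            "class_counts": {str(k): int(v) for k, v in self.class_counts.items()},
            "folds": self.folds.to_dict(orient="list"),
            "meta": {k: v for k, v in self.meta.items()
                     if isinstance(v, (int, float, str, bool))},
        }
        if self.per_level is not None:
            d["per_level"] = self.per_level.to_dict(orient="list")
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)


def _as_array(betas) -> np.ndarray:
    return np.asarray(getattr(betas, "data", betas), dtype=float)


def _final_predict(X_train, y_train, X_test, C) -> np.ndarray:
    """Train on (X_train, y_train), return +/-1 predictions for X_test."""
    K = X_train @ X_train.T
    alpha, rho = svm.solve_svc(K, y_train, C=C)
    f = svm.decision_values(X_test @ X_train.T, y_train, alpha, rho)
    return np.where(f > 0, 1, -1)


def nested_loocv_decode(betas, labels, mask: ROIMask,
                        sl_spec: SearchlightSpec | None = None,
                        clf_spec: ClassifierSpec | None = None,
                        feature_selection: str = "nested",
                        analysis: str = "nested-loocv",
                        roi: str | None = None) -> DecodingResult:
    """Leave-one-trial-out decoding with per-fold searchlight selection.

    For efficiency the per-fold searchlight maps are assembled from a
    shared leave-two-out table: for every sphere, a classifier is fitted on
    the trials excluding {i, j} and predicts both i and j. The inner LOO
    accuracy of sphere s in the outer fold holding out trial i is then the
    mean over j != i of the (i, j) entries — exactly the map that would be
    obtained by recomputing feature selection from scratch on that fold's
    n-1 training trials, since none of those fits ever touch trial i.

    ``feature_selection="all-trials"`` is a deliberately leaky diagnostic
    variant (selection on the full trial set before cross-validation) used
    to demonstrate that the nesting matters; it is never the default.
    """
    sl_spec = sl_spec or SearchlightSpec()
    clf_spec = clf_spec or sl_spec.classifier
    plan = CrossValidationPlan(len(np.asarray(labels)), feature_selection)
    X = _as_array(betas)
    y, classes = _encode_labels(labels)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("betas and labels disagree on trial count")
    counts = {classes[0]: int((y < 0).sum()), classes[1]: int((y > 0).sum())}
    if min(counts.values()) < 2:
        raise FoldDegeneracyError(
            "a class has < 2 trials; some training fold would lose it entirely")
    geom = MaskGeometry(mask, sl_spec.radius_voxels)
    if X.shape[1] != geom.n_voxels:
        raise ValueError("beta columns do not match mask voxel count")
    centers = geom.strided_centers(sl_spec.center_stride)
    # fixed trial ids scored as inner folds (None = all training trials)
    subset = _inner_subset(n, sl_spec.inner_subsample)

    if plan.feature_selection == "all-trials":
        amap = searchlight_map(X, labels, mask, sl_spec, geom=geom)
        fs_all = select_features(amap, sl_spec, geom=geom)

    else:
        # leave-two-out tables, one per sphere centre
        pair_tabs = {}
        for c in centers:
            idx = geom.spheres[c]
            Xs = X[:, idx]
            pair_tabs[c] = svm.pairwise_loo_correct(
                Xs @ Xs.T, y, C=clf_spec.C, predict_subset=subset)

    records = []
    for i in range(n):
        train = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        y_tr = y[train]
        if len(np.unique(y_tr)) < 2:
            raise FoldDegeneracyError(f"fold {i}: a class is absent from training")
        if plan.feature_selection == "all-trials":
            fs = fs_all
        else:
            if subset is None:
                inner = train
            else:
                inner = subset[subset != i]
            fold_counts = np.full(geom.n_voxels, -1, dtype=np.int64)
            for c in centers:
                fold_counts[c] = int(pair_tabs[c][i][inner].sum())
            n_inner = len(inner)
            amap_i = AccuracyMap(fold_counts, n_inner, centers, mask.label,
                                 train_trial_ids=train)
            fs = select_features(amap_i, sl_spec, geom=geom)
        pred = _final_predict(X[train][:, fs.voxel_ids], y_tr,
                              X[i:i + 1, fs.voxel_ids], clf_spec.C)[0]
        records.append({
            "test_trial": i,
            "true": classes[0] if y[i] < 0 else classes[1],
            "predicted": classes[0] if pred < 0 else classes[1],
            "correct": bool(pred == y[i]),
            "n_features": len(fs),
            "features": tuple(int(v) for v in fs.voxel_ids),
        })
    folds = pd.DataFrame.from_records(records)
    acc = float(folds["correct"].mean())
    return DecodingResult(
        analysis=analysis, roi=roi or mask.label, folds=folds, accuracy=acc,
        n_folds=n, class_counts=counts,
        meta={"feature_selection": plan.feature_selection,
              "mean_n_features": float(folds["n_features"].mean()),
              "radius_voxels": sl_spec.radius_voxels,
              "center_stride": sl_spec.center_stride},
    )


def cross_condition_decode(train_betas, train_labels, test_betas, test_labels,
                           mask: ROIMask,
                           sl_spec: SearchlightSpec | None = None,
                           clf_spec: ClassifierSpec | None = None,
                           analysis: str = "cross-condition",
                           roi: str | None = None) -> DecodingResult:
    """Train (with feature selection) on one condition set, test on another.

    Feature selection and classifier training use the train set only; the
    test set is evaluated in a single pass. Train and test must live in the
    same voxel space (same ROI mask).
    """
    sl_spec = sl_spec or SearchlightSpec()
    clf_spec = clf_spec or sl_spec.classifier
    X_tr = _as_array(train_betas)
    X_te = _as_array(test_betas)
    if X_tr.shape[1] != X_te.shape[1]:
        raise ValueError("train and test voxel spaces differ")
    y_tr, classes = _encode_labels(train_labels)
    test_labels = np.asarray(test_labels)
    if not np.all(np.isin(test_labels, classes)):
        raise ValueError("test labels outside the training classes")
    y_te = np.where(test_labels == classes[0], -1, 1).astype(np.int8)
    geom = MaskGeometry(mask, sl_spec.radius_voxels)
    if X_tr.shape[1] != geom.n_voxels:
        raise ValueError("beta columns do not match mask voxel count")
    amap = searchlight_map(X_tr, train_labels, mask, sl_spec, geom=geom)
    fs = select_features(amap, sl_spec, geom=geom)
    preds = _final_predict(X_tr[:, fs.voxel_ids], y_tr,
                           X_te[:, fs.voxel_ids], clf_spec.C)
    correct = preds == y_te
    folds = pd.DataFrame({
        "test_trial": np.arange(len(y_te)),
        "true": np.where(y_te < 0, classes[0], classes[1]),
        "predicted": np.where(preds < 0, classes[0], classes[1]),
        "correct": correct,
        "n_features": len(fs),
    })
    counts = {classes[0]: int((y_tr < 0).sum()), classes[1]: int((y_tr > 0).sum())}
    return DecodingResult(
        analysis=analysis, roi=roi or mask.label, folds=folds,
        accuracy=float(correct.mean()), n_folds=len(y_te), class_counts=counts,
        meta={"feature_selection": "train-set-only",
              "mean_n_features": float(len(fs)),
              "radius_voxels": sl_spec.radius_voxels},
    )


def morph_generalization(betas, trial_table: pd.DataFrame, mask: ROIMask,
                         sl_spec: SearchlightSpec | None = None,
                         clf_spec: ClassifierSpec | None = None,
                         test_levels=None,
                         roi: str | None = None) -> DecodingResult:
    """Train on 50% morph trials (choice labels), test on other morph levels.

    ``test_levels`` defaults to every non-50 morph condition present in the
    trial table (morph = strictly between 0 and 100 %A). Per-level and
    pooled accuracies are reported.
    """
    cond = np.asarray(trial_table["condition_pct_A"], dtype=float)
    X = _as_array(betas)
    train_rows = np.flatnonzero(cond == 50)
    if len(train_rows) == 0:
        raise ValueError("no 50% morph trials to train on")
    if test_levels is None:
        test_levels = sorted({c for c in cond if 0 < c < 100 and c != 50})
    test_levels = [float(lv) for lv in test_levels]
    if not test_levels:
        raise ValueError("test_levels is empty")
    if any(lv == 50 for lv in test_levels):
        raise ValueError("test_levels must exclude the 50% training level")
    missing = [lv for lv in test_levels if not np.any(cond == lv)]
    if missing:
        raise ValueError(f"no trials at requested level(s) {missing}")
    test_rows = np.flatnonzero(np.isin(cond, test_levels))
    choices = np.asarray(trial_table["choice"])
    res = cross_condition_decode(
        X[train_rows], choices[train_rows], X[test_rows], choices[test_rows],
        mask, sl_spec, clf_spec, analysis="morphgen", roi=roi)
    lvl = cond[test_rows]
    per_level = (pd.DataFrame({"level_pct_A": lvl,
                               "correct": res.folds["correct"].to_numpy()})
                 .groupby("level_pct_A", as_index=False)
                 .agg(n_trials=("correct", "size"), accuracy=("correct", "mean")))
    res.per_level = per_level
    res.folds["level_pct_A"] = lvl
    res.meta["test_levels"] = ",".join(str(lv) for lv in test_levels)
    return res


class DecodingModel:
    """MVPA decoding of one subject's beta series within one ROI.

    Parameters
    ----------
    betas
        (trials, mask voxels) beta series (array or ``BetaSeries``).
    trial_table
        Per-trial metadata with columns ``condition_pct_A`` and ``choice``.
    mask
        The ROI mask whose voxel list matches the beta columns.
    searchlight, classifier
        Specs for feature selection and the final classifier.
    label_by
        'choice' (default, as in the decision task) or 'stimulus'
        (diagnostic; labels by majority scene, excludes 50% trials).
    """

    def __init__(self, betas, trial_table: pd.DataFrame, mask: ROIMask,
                 searchlight: SearchlightSpec | None = None,
                 classifier: ClassifierSpec | None = None,
                 label_by: str = "choice"):
        if label_by not in ("choice", "stimulus"):
            raise ValueError("label_by must be 'choice' or 'stimulus'")
        self.betas = _as_array(betas)
        self.trial_table = trial_table.reset_index(drop=True)
        self.mask = mask
        self.searchlight = searchlight or SearchlightSpec()
        self.classifier = classifier or self.searchlight.classifier
        self.label_by = label_by
        if len(self.trial_table) != self.betas.shape[0]:
            raise ValueError("trial table and betas disagree on trial count")

    @classmethod
    def from_dataset(cls, dataset, roi_label: str, **kw) -> "DecodingModel":
        """Build from a synthetic dataset using its true patterns as betas."""
        return cls(dataset.true_patterns[roi_label], dataset.trial_table,
                   dataset.masks[roi_label], **kw)

    def _labels(self, rows: np.ndarray) -> np.ndarray:
        if self.label_by == "choice":
            return np.asarray(self.trial_table["choice"])[rows]
        cond = np.asarray(self.trial_table["condition_pct_A"], dtype=float)[rows]
        if np.any(cond == 50):
            raise ValueError("stimulus labels are undefined for 50% trials")
        return np.where(cond > 50, "A", "B")

    def _rows(self, levels) -> np.ndarray:
        cond = np.asarray(self.trial_table["condition_pct_A"], dtype=float)
        return np.flatnonzero(np.isin(cond, list(levels)))

    def fit(self, analysis: str = "100vs100", feature_selection: str = "nested",
            test_levels=None) -> DecodingResult:
        """Run one of the named analyses and return its result.

        ``100vs100`` / ``50vs50``: nested leave-one-trial-out decoding on
        the 100% scene trials / the 50% morph trials. ``train100_test50``
        and ``train50_test100``: cross-condition generalization.
        ``morphgen``: train on 50% morphs, test on the other morph levels.
        """
        if analysis not in ANALYSES:
            raise ValueError(f"unknown analysis {analysis!r}; choose from {ANALYSES}")
        if analysis == "100vs100":
            rows = self._rows([100, 0])
            return nested_loocv_decode(
                self.betas[rows], self._labels(rows), self.mask,
                self.searchlight, self.classifier, feature_selection,
                analysis=analysis, roi=self.mask.label)
        if analysis == "50vs50":
            rows = self._rows([50])
            return nested_loocv_decode(
                self.betas[rows], self._labels(rows), self.mask,
                self.searchlight, self.classifier, feature_selection,
                analysis=analysis, roi=self.mask.label)
        if analysis == "train100_test50":
            tr, te = self._rows([100, 0]), self._rows([50])
        elif analysis == "train50_test100":
            tr, te = self._rows([50]), self._rows([100, 0])
        else:  # morphgen
            return morph_generalization(
                self.betas, self.trial_table, self.mask, self.searchlight,
                self.classifier, test_levels=test_levels, roi=self.mask.label)
        return cross_condition_decode(
            self.betas[tr], self._labels(tr), self.betas[te], self._labels(te),
            self.mask, self.searchlight, self.classifier,
            analysis=analysis, roi=self.mask.label)
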