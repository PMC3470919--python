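"""ROI-restricted searchlight accuracy maps and maximal-sphere feature selection.

A searchlight sphere of radius r (default 3, in voxel index units; with
isotropic 1.5 mm voxels index and mm spheres coincide) is centred on each
ROI voxel and clipped to the ROI. The local multi-voxel pattern inside the
sphere is scored by leave-one-out cross-validated accuracy of a linear SVM
over the *training* trials supplied by the caller, yielding an accuracy
map. Feature selection returns the voxels of the maximal-accuracy sphere;
when several spheres tie for the maximum, the union of all maximal spheres
is returned. Ties are decided on integer correct counts, not floating
accuracies, so the union rule is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import svm
from .volumes import ROIMask

__all__ = [
    "ClassifierSpec",
    "SearchlightSpec",
    "AccuracyMap",
    "FeatureSet",
    "sphere_offsets",
    "sphere_indices",
    "searchlight_map",
    "select_features",
    "MaskGeometry",
]


class DegenerateLabelsError(ValueError):
    """Raised when a label class is absent from a training set."""


@dataclass(frozen=True)
class ClassifierSpec:
    """Linear maximum-margin classifier with hinge loss and fixed C.

    Only the linear kernel is supported; C defaults to 1 and there is no
    probability calibration.
    """

    C: float = 1.0
    kind: str = "linear-svc"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.kind != "linear-svc":
            raise ValueError("only the linear max-margin classifier is supported")


@dataclass(frozen=True)
class SearchlightSpec:
    """Searchlight feature-selection configuration.

    Parameters
    ----------
    radius_voxels
        Sphere radius in voxel index units (default 3).
    classifier
        The inner classifier; linear SVM with C=1.
    center_stride
        Evaluate sphere centres only on every ``stride``-th voxel along each
        grid axis. 1 (default) is the faithful mode covering every ROI voxel;
        larger strides are a speed knob for simulation studies.
    inner_subsample
        If set, score each sphere by leave-one-out over only this many
        (evenly spaced) training trials instead of all of them. ``None``
        (default) is the faithful mode.
    """

    radius_voxels: int = 3
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    center_stride: int = 1
    inner_subsample: int | None = None

    def __post_init__(self) -> None:
        if self.radius_voxels < 0:
            raise ValueError("radius_voxels must be >= 0")
        if self.center_stride < 1:
            raise ValueError("center_stride must be >= 1")
        if self.inner_subsample is not None and self.inner_subsample < 2:
            raise ValueError("inner_subsample must be >= 2 trials")


@lru_cache(maxsize=None)
def sphere_offsets(radius_voxels: int) -> np.ndarray:
    """Integer offsets (k, 3) with squared Euclidean norm <= radius^2."""
    r = int(radius_voxels)
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= r * r
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


class MaskGeometry:
    """Precomputed sphere memberships for one ROI mask.

    Voxels are numbered 0..n-1 in the C order of ``np.argwhere(mask)``;
    beta-series columns use the same order.
    """

    def __init__(self, mask: ROIMask, radius_voxels: int):
        self.mask = mask
        self.radius = int(radius_voxels)
        self.coords = mask.indices  # (n, 3)
        self.n_voxels = len(self.coords)
        lut = np.full(mask.mask.shape, -1, dtype=np.int64)
        lut[tuple(self.coords.T)] = np.arange(self.n_voxels)
        self._lut = lut
        self._spheres: list[np.ndarray] | None = None

    def sphere(self, voxel_id: int) -> np.ndarray:
        """Sorted in-mask voxel ids within the sphere centred on voxel_id."""
        center = self.coords[voxel_id]
        pts = center[None, :] + sphere_offsets(self.radius)
        shape = self.mask.mask.shape
        ok = np.all((pts >= 0) & (pts < np.array(shape)), axis=1)
        ids = self._lut[tuple(pts[ok].T)]
        return np.sort(ids[ids >= 0])

    @property
    def spheres(self) -> list[np.ndarray]:
        if self._spheres is None:
            self._spheres = [self.sphere(v) for v in range(self.n_voxels)]
        return self._spheres

    def strided_centers(self, stride: int) -> np.ndarray:
        """Voxel ids whose grid coordinates are multiples of ``stride``."""
        if stride == 1:
            return np.arange(self.n_voxels)
        keep = np.all(self.coords % stride == 0, axis=1)
        if not keep.any():  # degenerate masks: keep at least one centre
            keep[0] = True
        return np.flatnonzero(keep)


def sphere_indices(center, radius_voxels: int, mask: ROIMask) -> np.ndarray:
    """In-mask voxel ids within the radius-r sphere centred at ``center``.

    ``center`` is a 3-tuple of voxel coordinates and must lie inside the
    mask. Returned ids index the mask's voxel list (C order), the same
    numbering as beta-series columns.
    """
    center = np.asarray(center, dtype=int)
    if center.shape != (3,):
        raise ValueError("center must be a 3-vector of voxel coordinates")
    if not mask.mask[tuple(center)]:
        raise ValueError(f"center {tuple(center)} is outside the mask")
    geom = MaskGeometry(mask, radius_voxels)
    voxel_id = int(geom._lut[tuple(center)])
    return geom.sphere(voxel_id)


@dataclass
class AccuracyMap:
    """Per-voxel searchlight LOO accuracy over one ROI.

    ``correct_counts[v]`` is the number of correct inner-fold guesses for
    the sphere centred on voxel v and ``n_folds`` the number of inner folds,
    so ``values = correct_counts / n_folds``. Centres skipped by striding
    carry count -1 and value NaN.
    """

    correct_counts: np.ndarray
    n_folds: int
    centers: np.ndarray
    mask_label: str = ""
    train_trial_ids: np.ndarray | None = None

    @property
    def values(self) -> np.ndarray:
        vals = np.full(len(self.correct_counts), np.nan)
        ok = self.correct_counts >= 0
        vals[ok] = self.correct_counts[ok] / self.n_folds
        return vals

    def to_volume(self, mask: ROIMask) -> np.ndarray:
        """Scatter accuracies back onto the 3-D grid (NaN outside ROI)."""
        vol = np.full(mask.mask.shape, np.nan)
        vol[tuple(mask.indices.T)] = self.values
        return vol


@dataclass
class FeatureSet:
    """Voxel ids selected by the maximal-sphere rule."""

    voxel_ids: np.ndarray
    rule: str
    max_count: int
    n_folds: int
    tied_centers: np.ndarray

    def __len__(self) -> int:
        return len(self.voxel_ids)


def _encode_labels(labels) -> tuple[np.ndarray, np.ndarray]:
    """Map binary labels onto -1/+1 by sort order; return (y, classes)."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise DegenerateLabelsError(
            f"need exactly 2 label classes, got {list(classes)}"
        )
    y = np.where(labels == classes[0], -1, 1).astype(np.int8)
    return y, classes


def _inner_subset(n: int, subsample: int | None) -> np.ndarray | None:
    if subsample is None or subsample >= n:
        return None
    return np.unique(np.linspace(0, n - 1, subsample).round().astype(int))


def searchlight_map(train_betas, train_labels, mask: ROIMask,
                    spec: SearchlightSpec | None = None,
                    geom: MaskGeometry | None = None) -> AccuracyMap:
    """Leave-one-out searchlight accuracy map over the training trials.

    ``train_betas`` is (trials, mask voxels); only these trials are ever
    touched, so calling this inside an outer cross-validation fold with the
    fold's training set keeps the held-out trial fully unseen.
    """
    spec = spec or SearchlightSpec()
    X = np.asarray(getattr(train_betas, "data", train_betas), dtype=float)
    y, _ = _encode_labels(train_labels)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("betas and labels disagree on trial count")
    if min((y < 0).sum(), (y > 0).sum()) < 2:
        raise DegenerateLabelsError("need >= 2 trials per class for LOO scoring")
    geom = geom or MaskGeometry(mask, spec.radius_voxels)
    if X.shape[1] != geom.n_voxels:
        raise ValueError("beta columns do not match mask voxel count")
    subset = _inner_subset(n, spec.inner_subsample)
    centers = geom.strided_centers(spec.center_stride)
    counts = np.full(geom.n_voxels, -1, dtype=np.int64)
    for c in centers:
        idx = geom.spheres[c]
        Xs = X[:, idx]
        K = Xs @ Xs.T
        correct = svm.loo_correct(K, y, C=spec.classifier.C)
        counts[c] = int(correct.sum()) if subset is None else int(correct[subset].sum())
    n_folds = n if subset is None else len(subset)
    return AccuracyMap(correct_counts=counts, n_folds=n_folds, centers=centers,
                       mask_label=mask.label)


def select_features(amap: AccuracyMap, spec: SearchlightSpec | None = None,
                    mask: ROIMask | None = None,
                    geom: MaskGeometry | None = None) -> FeatureSet:
    """Voxels of the maximal-accuracy sphere; union of spheres on ties."""
    spec = spec or SearchlightSpec()
    if geom is None:
        if mask is None:
            raise ValueError("need mask or geom to resolve sphere membership")
        geom = MaskGeometry(mask, spec.radius_voxels)
    counts = amap.correct_counts
    evaluated = np.flatnonzero(counts >= 0)
    if len(evaluated) == 0:
        raise ValueError("accuracy map has no evaluated centers")
    max_count = int(counts[evaluated].max())
    tied = evaluated[counts[evaluated] == max_count]
    voxels = np.unique(np.concatenate([geom.spheres[c] for c in tied]))
    rule = "max-sphere" if len(tied) == 1 else "max-sphere-tie-union"
    return FeatureSet(voxel_ids=voxels, rule=rule, max_count=max_count,
                      n_folds=amap.n_folds, tied_centers=tied)
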