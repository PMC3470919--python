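"""Trial-wise beta estimation: canonical HRF, design matrices, OLS betas.

Each trial is modeled as a separate regressor: a delta function at the
trial onset convolved with the canonical double-gamma hemodynamic response
function and sampled at scan times (TR grid). Betas are ordinary
least-squares estimates computed for all trial regressors simultaneously;
noise is treated as i.i.d. (no autocorrelation whitening), matching the
synthesis model used by the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .volumes import ROIMask, Volume

__all__ = [
    "HRFSpec",
    "DesignMatrix",
    "BetaSeries",
    "canonical_hrf",
    "hrf_value",
    "build_design",
    "estimate_betas",
    "synthesize_bold",
]


class EstimationError(ValueError):
    """Raised for rank-deficient designs, naming the collinear columns."""


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma HRF parameters (SPM convention).

    The kernel is the difference of two gamma densities: a positive lobe
    peaking ~5 s after onset (delay 6 s, dispersion 1 s) minus an
    undershoot (delay 16 s, dispersion 1 s) scaled by 1/6; it is
    peak-normalized to 1 and truncated at ``duration_s``.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration_s: float = 32.0
    dt_s: float = 0.1

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


def _raw_hrf(spec: HRFSpec, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    pos = stats.gamma.pdf(t, spec.peak_delay_s / spec.peak_dispersion_s,
                          scale=spec.peak_dispersion_s)
    neg = stats.gamma.pdf(t, spec.undershoot_delay_s / spec.undershoot_dispersion_s,
                          scale=spec.undershoot_dispersion_s)
    h = pos - spec.undershoot_ratio * neg
    return np.where(t < 0, 0.0, h)


def _peak_value(spec: HRFSpec) -> float:
    tt = np.arange(0, spec.duration_s, spec.dt_s)
    return float(_raw_hrf(spec, tt).max())


def hrf_value(spec: HRFSpec, t) -> np.ndarray:
    """Peak-normalized HRF evaluated at arbitrary times (0 outside support)."""
    h = _raw_hrf(spec, np.asarray(t, dtype=float)) / _peak_value(spec)
    return np.where(np.asarray(t, dtype=float) >= spec.duration_s, 0.0, h)


def canonical_hrf(spec: HRFSpec | None = None):
    """Sampled canonical HRF kernel.

    Returns ``(t, h)`` with t on the dt grid over [0, duration) and h
    peak-normalized to 1.
    """
    spec = spec or HRFSpec()
    t = np.arange(0, spec.duration_s, spec.dt_s)
    return t, _raw_hrf(spec, t) / _peak_value(spec)


@dataclass
class DesignMatrix:
    """Scans x regressors matrix; one column per trial plus nuisance."""

    X: np.ndarray
    trial_columns: np.ndarray  # column indices of trial regressors, in trial order
    tr_s: float
    onsets_s: np.ndarray
    nuisance_names: list = field(default_factory=list)

    @property
    def n_scans(self) -> int:
        return self.X.shape[0]

    @property
    def n_trials(self) -> int:
        return len(self.trial_columns)


def build_design(onsets_s, n_scans: int, tr_s: float,
                 hrf: HRFSpec | None = None,
                 nuisance: np.ndarray | None = None,
                 add_intercept: bool = True) -> DesignMatrix:
    """One HRF-convolved event regressor per trial, plus nuisance columns.

    Trial j's regressor is the canonical HRF shifted to the trial onset and
    sampled at scan acquisition times ``t = TR * (0..n_scans-1)``. Motion
    or other nuisance regressors (scans x q) are appended after the trial
    columns, followed by an intercept unless disabled.
    """
    hrf = hrf or HRFSpec()
    onsets = np.asarray(onsets_s, dtype=float)
    if onsets.ndim != 1 or len(onsets) == 0:
        raise ValueError("onsets_s must be a nonempty 1-D array")
    run_end = n_scans * tr_s
    if np.any(onsets < 0) or np.any(onsets >= run_end):
        raise ValueError("trial onset beyond run end")
    scan_t = np.arange(n_scans) * tr_s
    cols = [hrf_value(hrf, scan_t - on) for on in onsets]
    names: list = []
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_scans:
            raise ValueError("nuisance rows must equal n_scans")
        cols.extend(nuisance.T)
        names.extend(f"nuisance_{q}" for q in range(nuisance.shape[1]))
    if add_intercept:
        cols.append(np.ones(n_scans))
        names.append("intercept")
    X = np.column_stack(cols)
    return DesignMatrix(X=X, trial_columns=np.arange(len(onsets)), tr_s=tr_s,
                        onsets_s=onsets, nuisance_names=names)


@dataclass
class BetaSeries:
    """Per-trial response amplitudes: trials x voxels, aligned to a mask."""

    data: np.ndarray
    mask: ROIMask | None = None
    trial_table: object | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("beta series must be trials x voxels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("beta series contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


def _collinear_columns(X: np.ndarray) -> list:
    """Best-effort identification of dependent columns via QR pivots."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return sorted(int(piv[k]) for k in range(len(diag)) if diag[k] <= tol)


def estimate_betas(timeseries, design: DesignMatrix,
                   mask: ROIMask | None = None,
                   trial_table=None) -> BetaSeries:
    """OLS betas per voxel; returns trial rows only (nuisance dropped).

    ``timeseries`` is a 4-D :class:`Volume` (scans on the last axis, voxels
    taken from ``mask``) or a (scans, voxels) array.
    """
    if isinstance(timeseries, Volume):
        if timeseries.data.ndim != 4:
            raise ValueError("timeseries volume must be 4-D")
        if mask is None:
            raise ValueError("mask required to extract voxels from a 4-D volume")
        Y = timeseries.data[mask.mask].T  # scans x voxels
    else:
        Y = np.asarray(timeseries, dtype=float)
    X = design.X
    if Y.shape[0] != X.shape[0]:
        raise ValueError("scan count mismatch between timeseries and design")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X)
        raise EstimationError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear column(s): {bad}")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return BetaSeries(beta[design.trial_columns], mask=mask, trial_table=trial_table)


def synthesize_bold(design: DesignMatrix, trial_patterns: np.ndarray,
                    noise_sd: float = 0.0, rng: np.random.Generator | None = None,
                    nuisance_betas: np.ndarray | None = None) -> np.ndarray:
    """Forward model: scans x voxels BOLD from per-trial amplitude patterns.

    ``Y = X_trials @ patterns (+ X_nuisance @ nuisance_betas) + N(0, sd^2)``.
    """
    P = np.asarray(trial_patterns, dtype=float)
    if P.shape[0] != design.n_trials:
        raise ValueError("pattern rows must equal trial count")
    Y = design.X[:, design.trial_columns] @ P
    other = np.setdiff1d(np.arange(design.X.shape[1]), design.trial_columns)
    if nuisance_betas is not None:
        Y = Y + design.X[:, other] @ np.asarray(nuisance_betas, dtype=float)
    if noise_sd > 0:
        rng = rng or np.random.default_rng()
        Y = Y + rng.normal(scale=noise_sd, size=Y.shape)
    return Y
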