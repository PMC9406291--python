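"""Common spatial patterns per sub-band: covariance estimation, generalized
eigendecomposition and variance-feature extraction.

For a two-class problem with class-mean covariance matrices ``C1`` and
``C2``, CSP maximizes (and minimizes) the Rayleigh quotient
``J(w) = (w' C1 w) / (w' C2 w)``.  The stationary points are the generalized
eigenvectors of the pencil ``(C1, C2)`` -- equivalently eigenvectors of
``inv(C2) @ C1`` -- and the spatial filter matrix ``W`` collects the
eigenvectors of the largest and smallest generalized eigenvalues, where the
two classes' variance ratio is most extreme.

Features per trial are the filtered variances ``z = diag(W' X X' W)``,
optionally log-normalized as ``log(z / sum(z))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .containers import EpochArray

__all__ = [
    "ClassCovariancePair",
    "SpatialFilters",
    "SubbandFeatures",
    "trial_covariances",
    "class_covariances",
    "csp_eig",
    "selection_indices",
    "fit_csp",
    "extract_features",
    "features_from_covariances",
    "topography_to_csv",
]


@dataclass
class ClassCovariancePair:
    """Class-mean spatial covariance matrices (symmetric PSD, N x N)."""

    C1: np.ndarray
    C2: np.ndarray

    def __post_init__(self) -> None:
        for name, C in (("C1", self.C1), ("C2", self.C2)):
            C = np.asarray(C, dtype=np.float64)
            if C.ndim != 2 or C.shape[0] != C.shape[1]:
                raise ValueError(f"{name} must be square, got shape {C.shape}")
            if not np.allclose(C, C.T, atol=1e-10 * max(1.0, np.abs(C).max())):
                raise ValueError(f"{name} is not symmetric")
        if self.C1.shape != self.C2.shape:
            raise ValueError("C1 and C2 must have the same shape")

    @property
    def n_channels(self) -> int:
        return self.C1.shape[0]


@dataclass
class SpatialFilters:
    """Fitted CSP filters for one sub-band.

    Attributes
    ----------
    filters : ndarray, shape (n_channels, n_filters)
        Columns are generalized eigenvectors of ``(C1, C2)``, scaled so that
        ``w' (C1 + C2) w = 1``.  The first ``ceil(n_filters/2)`` columns
        correspond to the largest eigenvalues (descending), the remaining
        ``floor(n_filters/2)`` to the smallest (ascending).
    eigvals : ndarray, shape (n_channels,)
        Full generalized eigenvalue spectrum of ``(C1, C2)``, sorted
        descending.
    selected : ndarray, shape (n_filters,)
        Indices into ``eigvals`` of the retained columns, in column order.
    band_index : int
        Position of the sub-band in its filter bank (-1 if standalone).
    """

    filters: np.ndarray
    eigvals: np.ndarray
    selected: np.ndarray
    band_index: int = -1

    @property
    def n_filters(self) -> int:
        return self.filters.shape[1]

    @property
    def selected_eigvals(self) -> np.ndarray:
        return self.eigvals[self.selected]


@dataclass
class SubbandFeatures:
    """Per-trial CSP variance features for one sub-band."""

    values: np.ndarray  # (n_trials, n_filters)
    band_index: int = -1
    log_transformed: bool = False


def trial_covariances(
    epochs: EpochArray, center: bool = False, normalize_trace: bool = True
) -> np.ndarray:
    """Per-trial spatial covariance matrices, shape (n_trials, N, N).

    Each trial contributes ``X @ X.T`` (after optional mean-centering of each
    channel), divided by its trace when ``normalize_trace`` so that every
    trial carries unit total power.  Without trace normalization the raw
    scatter matrix ``X @ X.T`` is returned (no 1/L factor).
    """
    X = epochs.data
    if center:
        X = X - X.mean(axis=-1, keepdims=True)
    C = np.einsum("tcs,tds->tcd", X, X)
    if normalize_trace:
        tr = np.trace(C, axis1=1, axis2=2)
        if np.any(tr <= 0):
            warnings.warn("trial with zero total power; trace normalization skipped for it")
        safe = np.where(tr > 0, tr, 1.0)
        C = C / safe[:, None, None]
    return C


def class_covariances(
    band_epochs: EpochArray, center: bool = False, normalize_trace: bool = True
) -> ClassCovariancePair:
    """Arithmetic class means of per-trial covariances.

    Class 1 is the smaller label value, class 2 the larger (by the package
    convention 1 = movement imagery, 2 = rest).

    Raises
    ------
    ValueError
        If fewer or more than two classes are present, or a class is empty.

    Warns
    -----
    UserWarning
        If trials have no more samples than channels (rank-deficient
        covariances) or zero power.
    """
    classes = band_epochs.classes
    if classes.size != 2:
        raise ValueError(f"exactly two classes required, got {classes.tolist()}")
    if band_epochs.n_samples <= band_epochs.n_channels:
        warnings.warn(
            f"trials have {band_epochs.n_samples} samples for "
            f"{band_epochs.n_channels} channels: covariances are rank-deficient"
        )
    C = trial_covariances(band_epochs, center=center, normalize_trace=normalize_trace)
    m1 = band_epochs.labels == classes[0]
    return ClassCovariancePair(C[m1].mean(axis=0), C[~m1].mean(axis=0))


def _shrink(C: np.ndarray, gamma: float) -> np.ndarray:
    n = C.shape[0]
    return (1.0 - gamma) * C + gamma * (np.trace(C) / n) * np.eye(n)


def csp_eig(cov: ClassCovariancePair, shrinkage: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Full generalized eigendecomposition of the CSP pencil ``(C1, C2)``.

    Returns ``(eigvals, V)`` with eigenvalues sorted descending and columns
    of ``V`` normalized to ``v' (C1 + C2) v = 1``.
    """
    C1 = _shrink(np.asarray(cov.C1, dtype=np.float64), shrinkage)
    C2 = _shrink(np.asarray(cov.C2, dtype=np.float64), shrinkage)
    try:
        mu, V = scipy.linalg.eigh(C1, C1 + C2)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError(
            "C1 + C2 is singular; increase the shrinkage regularization"
        ) from exc
    order = np.argsort(mu, kind="stable")[::-1]
    mu = mu[order]
    V = V[:, order]
    lam = mu / np.maximum(1.0 - mu, np.finfo(float).tiny)
    return lam, V


def selection_indices(n_channels: int, n_filters: int) -> np.ndarray:
    """Column picks into a descending eigenvalue ordering: the
    ``ceil(Ns/2)`` largest followed by the ``floor(Ns/2)`` smallest
    (smallest first)."""
    n_top = (n_filters + 1) // 2
    n_bot = n_filters // 2
    return np.concatenate(
        [np.arange(n_top), np.arange(n_channels - n_bot, n_channels)[::-1]]
    )


def fit_csp(
    cov: ClassCovariancePair,
    n_filters: int,
    shrinkage: float = 1e-6,
    band_index: int = -1,
) -> SpatialFilters:
    """Solve the CSP generalized eigenproblem and keep the extremal filters.

    Solves ``C1 w = lam * C2 w`` via the symmetric-definite formulation
    ``C1 w = mu * (C1 + C2) w`` (with ``lam = mu / (1 - mu)``), which scipy
    solves with eigenvectors normalized to ``w' (C1 + C2) w = 1``.  Keeps
    the ``ceil(n_filters/2)`` eigenvectors of largest eigenvalue and the
    ``floor(n_filters/2)`` of smallest.

    Parameters
    ----------
    cov : ClassCovariancePair
    n_filters : int
        Number of spatial filters Ns, ``1 <= Ns <= N``.  Odd values keep one
        more filter from the large-eigenvalue end.
    shrinkage : float
        Diagonal loading ``C <- (1-g) C + g (tr(C)/N) I`` applied to both
        class matrices for numerical stability.

    Raises
    ------
    ValueError
        If ``n_filters`` is out of range or the covariance sum is singular
        even after shrinkage (increase ``shrinkage``).
    """
    N = cov.n_channels
    if not (1 <= n_filters <= N):
        raise ValueError(f"n_filters must be in [1, {N}], got {n_filters}")
    lam, V = csp_eig(cov, shrinkage)
    sel = selection_indices(N, n_filters)
    return SpatialFilters(
        filters=V[:, sel].copy(), eigvals=lam, selected=sel, band_index=band_index
    )


def extract_features(
    filters: SpatialFilters,
    band_epochs: EpochArray,
    log_transform: bool = True,
) -> SubbandFeatures:
    """Variance features ``z = diag(W' X X' W)`` per trial.

    With ``log_transform`` the variances are sum-normalized then logged:
    ``z <- log(z / sum(z))``, making the features invariant to global signal
    scale.  Non-positive variances under the log are floored at
    ``1e-15 * sum(z)`` (a trial with zero total projected power is an error).
    """
    W = filters.filters
    if band_epochs.n_channels != W.shape[0]:
        raise ValueError(
            f"epochs have {band_epochs.n_channels} channels but filters expect {W.shape[0]}"
        )
    P = np.einsum("ck,tcs->tks", W, band_epochs.data)
    z = np.sum(P * P, axis=-1)  # (n_trials, n_filters)
    if log_transform:
        z = _log_normalize(z)
    return SubbandFeatures(values=z, band_index=filters.band_index, log_transformed=log_transform)


def _log_normalize(z: np.ndarray) -> np.ndarray:
    """log(z / sum(z)) row-wise with an epsilon floor of 1e-15 * sum(z)."""
    total = z.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("trial with zero total projected variance; cannot log-transform")
    frac = z / total
    return np.log(np.maximum(frac, 1e-15))


def features_from_covariances(
    filters: SpatialFilters, trial_cov: np.ndarray, log_transform: bool = True
) -> np.ndarray:
    """Features computed from precomputed per-trial scatter matrices.

    Equivalent to :func:`extract_features` when ``trial_cov[t] = X_t @ X_t.T``
    (log-normalized features are additionally invariant to any per-trial
    positive rescaling of the matrices, e.g. trace normalization).
    """
    W = filters.filters
    z = np.einsum("ck,tcd,dk->tk", W, trial_cov, W)
    z = np.maximum(z, 0.0)
    return _log_normalize(z) if log_transform else z


def topography_to_csv(filters: SpatialFilters, path, channel_names=None) -> None:
    """Export filter weights as CSV (one row per channel, one column per filter)."""
    N = filters.filters.shape[0]
    names = channel_names if channel_names is not None else [f"ch{i}" for i in range(N)]
    df = pd.DataFrame(
        filters.filters, columns=[f"filter_{k}" for k in range(filters.n_filters)]
    )
    df.insert(0, "channel", names)
    df.to_csv(path, index=False)
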