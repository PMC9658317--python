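"""Common spatial patterns: discriminative spatial filters and log-variance
features.

CSP seeks spatial filters ``w`` maximizing the Rayleigh quotient
``w' S1 w / w' S2 w`` of the two class-average covariance matrices — the
generalized eigenproblem ``S1 w = lam S2 w``.  The M filters with the
largest and M with the smallest generalized eigenvalues concentrate
variance of one class while suppressing the other; per trial, the natural
log of the variance of each filtered signal is the feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .trial_store import TrialSet

__all__ = [
    "ClassCovariances",
    "SpatialFilterBank",
    "FeatureBlock",
    "trial_covariance",
    "class_covariances",
    "fit_csp",
    "log_variance_features",
]

#: relative ridge added to the denominator covariance before the eigensolve
DEFAULT_RIDGE = 1e-8


@dataclass
class ClassCovariances:
    """Trace-normalized class-average spatial covariances."""

    sigma1: np.ndarray
    sigma2: np.ndarray
    n1: int
    n2: int


@dataclass
class SpatialFilterBank:
    """2M unit-norm spatial filters, M most class-1 then M most class-2.

    ``eigenvalues`` holds the corresponding generalized eigenvalues, the
    first M sorted descending (largest Rayleigh quotients), the last M the
    smallest.
    """

    W: np.ndarray  # (C, 2M)
    eigenvalues: np.ndarray  # (2M,)
    M: int

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]


@dataclass
class FeatureBlock:
    """trials x 2M log-variance features from one (segment, band) cell."""

    values: np.ndarray
    provenance: tuple[int, int] | None = None


def trial_covariance(X) -> np.ndarray:
    """Trace-normalized spatial covariance ``X X' / trace(X X')`` of one trial."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError(f"expected channels x samples with >= 2 samples, got {X.shape}")
    S = X @ X.T
    tr = np.trace(S)
    if tr <= 0 or not np.isfinite(tr):
        raise ValueError("degenerate trial: zero (or non-finite) total power")
    return S / tr


def class_covariances(segment: TrialSet) -> ClassCovariances:
    """Arithmetic mean of per-trial normalized covariances within each class."""
    segment.validate(require_both_classes=True)
    sigmas = {}
    counts = {}
    for label in (1, 2):
        idx = segment.class_indices(label)
        acc = np.zeros((segment.n_channels, segment.n_channels))
        for i in idx:
            acc += trial_covariance(segment.data[i])
        sigmas[label] = acc / len(idx)
        counts[label] = len(idx)
    return ClassCovariances(
        sigma1=sigmas[1], sigma2=sigmas[2], n1=counts[1], n2=counts[2]
    )


def fit_csp(cov: ClassCovariances, M: int, ridge: float = DEFAULT_RIDGE) -> SpatialFilterBank:
    """Solve ``S1 w = lam S2 w`` and keep the M extreme eigenvectors per side.

    A ridge of ``ridge * trace(S2)/C`` is added to S2 for conditioning.
    Filters are rescaled to unit Euclidean norm (the eigenproblem leaves
    scale free) and their sign fixed so the largest-magnitude coefficient
    is positive; eigenvalue ties break by ascending original index.
    """
    C = cov.sigma1.shape[0]
    if not 1 <= 2 * M <= C:
        raise ValueError(f"need 1 <= 2M <= C, got M={M}, C={C}")
    S2 = cov.sigma2 + ridge * (np.trace(cov.sigma2) / C) * np.eye(C)
    try:
        w, v = scipy.linalg.eigh(cov.sigma1, S2)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - pathological
        raise ValueError(f"class-2 covariance numerically singular: {exc}") from exc
    order = np.argsort(-w, kind="stable")
    sel = np.concatenate([order[:M], order[-M:]])
    eigvals = w[sel]
    W = v[:, sel].copy()
    W /= np.linalg.norm(W, axis=0, keepdims=True)
    for col in range(W.shape[1]):
        peak = np.argmax(np.abs(W[:, col]))
        if W[peak, col] < 0:
            W[:, col] = -W[:, col]
    return SpatialFilterBank(W=W, eigenvalues=eigvals, M=M)


def log_variance_features(segment: TrialSet, bank: SpatialFilterBank) -> FeatureBlock:
    """Natural-log population variance of each spatially filtered trial.

    ``Z = W' X`` per trial; feature i is ``log(var(Z_i))``.  No variance
    normalization is applied before the log; the downstream margin
    classifier absorbs the affine freedom.
    """
    if bank.n_channels != segment.n_channels:
        raise ValueError(
            f"filter bank built for {bank.n_channels} channels, "
            f"segment has {segment.n_channels}"
        )
    Z = np.einsum("ck,ncp->nkp", bank.W, segment.data)
    var = Z.var(axis=-1)  # population variance (ddof=0)
    if np.any(var <= 0):
        raise ValueError("degenerate feature: a projected signal has zero variance")
    return FeatureBlock(values=np.log(var))
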