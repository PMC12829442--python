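"""Distribution-shift and calibration analytics.

Implements the squared Fréchet (Wasserstein-2) distance between Gaussian
summaries of embedded molecule sets — the core of the Fréchet ChemNet
Distance (FCD), with the embedder injected so any fixed-length representation
can stand in for a pretrained chemical network — plus a bootstrap
internal-FCD baseline, the Expected Normalized Calibration Error (ENCE) with
its per-bin calibration-curve data, and a plug-in Shannon diversity entropy
over categorical molecule descriptors (scaffolds, functional groups, ...).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .datasets import feature_matrix

__all__ = [
    "GaussianSummary",
    "CalibrationBin",
    "frechet_distance",
    "fcd_between_sets",
    "bootstrap_internal_fcd",
    "ence",
    "diversity_entropy",
    "standardized_identity_embedding",
]

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-10


@dataclass
class GaussianSummary:
    """Mean/covariance summary of an embedded sample."""

    mean: np.ndarray
    cov: np.ndarray
    n: int

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = np.asarray(self.cov, dtype=float)
        d = self.mean.shape[0]
        if self.cov.shape != (d, d):
            raise ValueError("covariance shape does not match mean dimension")
        if not np.allclose(self.cov, self.cov.T, atol=_SYM_TOL):
            raise ValueError("covariance not symmetric within tolerance")

    @classmethod
    def from_samples(cls, Z: np.ndarray, jitter: float = 0.0) -> "GaussianSummary":
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        mean = Z.mean(axis=0)
        cov = np.cov(Z, rowvar=False)
        cov = np.atleast_2d(cov)
        cov = 0.5 * (cov + cov.T)
        if jitter > 0:
            cov = cov + jitter * np.eye(cov.shape[0])
        return cls(mean=mean, cov=cov, n=Z.shape[0])


def _psd_sqrt(cov: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition with clamping."""
    vals, vecs = np.linalg.eigh(cov)
    if np.min(vals) < -1e-8 * max(1.0, np.max(np.abs(vals))):
        raise ValueError("covariance has significantly negative eigenvalues")
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def frechet_distance(a: GaussianSummary, b: GaussianSummary) -> float:
    """Squared Fréchet distance between two Gaussians,

        d^2 = ||mu_a - mu_b||^2 + Tr(S_a + S_b - 2 (S_a S_b)^{1/2}).

    The cross term is evaluated as Tr of the PSD square root of
    S_a^{1/2} S_b S_a^{1/2}, which is numerically robust for near-singular
    covariances.
    """
    if a.mean.shape != b.mean.shape:
        raise ValueError("dimension mismatch between summaries")
    diff = a.mean - b.mean
    a_half = _psd_sqrt(a.cov)
    inner = a_half @ b.cov @ a_half
    vals = np.linalg.eigvalsh(0.5 * (inner + inner.T))
    vals = np.clip(vals, 0.0, None)
    cross = np.sum(np.sqrt(vals))
    d2 = float(diff @ diff + np.trace(a.cov) + np.trace(b.cov) - 2.0 * cross)
    return max(d2, 0.0)


def standardized_identity_embedding(X: np.ndarray, Y: np.ndarray):
    """Default embedder: z-score both sets with their pooled statistics."""
    pooled = np.vstack([X, Y])
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return (X - mu) / sd, (Y - mu) / sd


def _as_matrix(data) -> np.ndarray:
    if hasattr(data, "columns"):
        return feature_matrix(data)
    return np.atleast_2d(np.asarray(data, dtype=float))


def fcd_between_sets(X, Y, embed: Optional[Callable] = None) -> float:
    """Fréchet distance between the Gaussian summaries of two embedded sets.

    ``embed`` maps a feature matrix to an embedding matrix; by default the
    standardized feature vectors themselves are the embedding (pooled
    z-scoring), so the metric is scale-free without any pretrained network.
    Lower values indicate more similar sets.
    """
    Xm, Ym = _as_matrix(X), _as_matrix(Y)
    if embed is not None:
        Ze_x, Ze_y = np.atleast_2d(embed(Xm)), np.atleast_2d(embed(Ym))
    else:
        Ze_x, Ze_y = standardized_identity_embedding(Xm, Ym)
    d = Ze_x.shape[1]
    if min(len(Ze_x), len(Ze_y)) <= d:
        logger.warning("sample size <= embedding dimension; covariance is degenerate")
    jitter = 0.0
    a = GaussianSummary.from_samples(Ze_x)
    b = GaussianSummary.from_samples(Ze_y)
    if (np.linalg.matrix_rank(a.cov) < d) or (np.linalg.matrix_rank(b.cov) < d):
        jitter = 1e-6
        logger.info("degenerate covariance; adding diagonal jitter %.0e", jitter)
        a = GaussianSummary.from_samples(Ze_x, jitter=jitter)
        b = GaussianSummary.from_samples(Ze_y, jitter=jitter)
    return frechet_distance(a, b)


def bootstrap_internal_fcd(X, n_boot: int = 20, seed: int = 0,
                           embed: Optional[Callable] = None):
    """Internal FCD baseline: split the set into random disjoint halves
    ``n_boot`` times and report (mean, sd) of the half-vs-half FCD."""
    Xm = _as_matrix(X)
    n = len(Xm)
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_boot):
        perm = rng.permutation(n)
        half = n // 2
        vals.append(fcd_between_sets(Xm[perm[:half]], Xm[perm[half:2 * half]], embed=embed))
    vals = np.asarray(vals)
    return float(vals.mean()), float(vals.std(ddof=1))


@dataclass
class CalibrationBin:
    """One variance-sorted calibration bin: root mean predicted variance
    (RMV) vs. empirical RMSE."""

    rmv: float
    rmse: float
    count: int


def ence(predictions, n_bins: int = 10):
    """Expected Normalized Calibration Error over variance-sorted bins.

    ``predictions`` is a sequence of (predicted variance, squared error)
    pairs.  Predictions are sorted by predicted variance and split into
    ``n_bins`` equal-count bins (remainder to the last bin); per bin
    RMV_k = sqrt(mean variance), RMSE_k = sqrt(mean squared error), and

        ENCE = (1/K) sum_k |RMV_k - RMSE_k| / RMV_k.

    Returns the scalar ENCE and the per-bin calibration-curve data.
    """
    arr = np.asarray(list(predictions), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("predictions must be (variance, squared_error) pairs")
    if np.any(arr[:, 0] <= 0):
        raise ValueError("predicted variances must be positive")
    n = arr.shape[0]
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n < n_bins:
        raise ValueError(f"{n} predictions for {n_bins} bins")
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    size = n // n_bins
    bins = []
    errs = []
    for k in range(n_bins):
        lo = k * size
        hi = (k + 1) * size if k < n_bins - 1 else n
        chunk = arr[lo:hi]
        rmv = float(np.sqrt(chunk[:, 0].mean()))
        rmse = float(np.sqrt(chunk[:, 1].mean()))
        bins.append(CalibrationBin(rmv=rmv, rmse=rmse, count=hi - lo))
        errs.append(abs(rmv - rmse) / rmv)
    return float(np.mean(errs)), bins


def diversity_entropy(categories) -> float:
    """Plug-in Shannon entropy (natural log) of a categorical sample."""
    labels = list(categories)
    if not labels:
        raise ValueError("empty category list")
    _, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))
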