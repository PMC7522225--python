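"""PCA in the tangent space at the Karcher mean of a sample of SRTs.

Each subject's SRT is mapped to the tangent space at the sample Karcher mean
by the inverse-exponential map; rows are scaled by the square roots of the
trapezoidal quadrature weights so that Euclidean dot products in the matrix
equal L2 inner products of the underlying tangent functions.  An SVD of the
(optionally row-centred) matrix yields orthonormal principal directions,
singular values, and per-subject scores that serve as Euclidean predictors
downstream.  The number of retained components is the smallest count whose
cumulative squared-singular-value fraction reaches the variance threshold
(99.99% by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sphere_geometry import (
    DensityFunction,
    SRTFunction,
    TangentVector,
    _log_rows,
    exp_map,
    inverse_srt,
    log_map,
    trapezoid_weights,
)

__all__ = [
    "TangentPCAModel",
    "tangent_matrix",
    "fit_tangent_pca",
    "fit",
    "project",
    "principal_path",
]

DEFAULT_VARIANCE_THRESHOLD = 0.9999


@dataclass
class TangentPCAModel:
    """Karcher mean, principal directions, and scores of a tangent-space PCA.

    ``directions`` has orthonormal rows in the quadrature-weighted
    coordinates (multiply by 1/sqrt(w) to read them as tangent functions).
    ``scores`` are the projections of the (centred) weighted tangent rows.
    """

    directions: np.ndarray        # (r, m) in weighted coordinates
    singular_values: np.ndarray   # (r,)
    scores: np.ndarray            # (n, r)
    variance_fractions: np.ndarray
    cumulative_variance: np.ndarray
    total_variance: float
    r: int
    n: int
    row_mean: np.ndarray          # (m,) weighted-coordinate centring offset
    base_mean: SRTFunction | None = None
    centered: bool = True

    @property
    def quad_sqrt(self) -> np.ndarray:
        return np.sqrt(trapezoid_weights(self.row_mean.size))


def tangent_matrix(mean: SRTFunction, hs: Sequence[SRTFunction]) -> np.ndarray:
    """Stacked, quadrature-weighted inverse-exponential maps at the mean.

    Row i is log_mean(h_i) scaled by sqrt(w), so each row's Euclidean norm
    equals the geodesic distance d(mean, h_i) and row dot products equal L2
    inner products of the tangent functions.
    """
    for h in hs:
        if h.values.shape != mean.values.shape or not np.array_equal(h.grid, mean.grid):
            raise ValueError("grid mismatch between mean and sample SRTs")
    H = np.stack([h.values for h in hs])
    wq = trapezoid_weights(mean.values.size)
    return _log_rows(mean.values, H, wq) * np.sqrt(wq)


def fit_tangent_pca(
    V: np.ndarray,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    *,
    base_mean: SRTFunction | None = None,
    center: bool = True,
) -> TangentPCAModel:
    """SVD of the (row-centred) tangent matrix; retain the leading components.

    Deterministic up to sign, with the sign fixed so each direction's
    largest-magnitude coordinate is positive.  On a discrete grid the
    tangent vectors at the Karcher mean average to approximately (not
    exactly) zero, so row-centring keeps the PCA well defined; the
    uncentred variant is available via ``center=False``.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[0] < 2:
        raise ValueError("tangent PCA needs at least 2 subjects")
    n, m = V.shape
    row_mean = V.mean(axis=0) if center else np.zeros(m)
    Vc = V - row_mean
    _, s, Vt = np.linalg.svd(Vc, full_matrices=False)
    total = float((s**2).sum())
    if total < 1e-28:
        # degenerate sample: all subjects at the mean
        return TangentPCAModel(
            directions=np.zeros((0, m)),
            singular_values=np.zeros(0),
            scores=np.zeros((n, 0)),
            variance_fractions=np.zeros(0),
            cumulative_variance=np.zeros(0),
            total_variance=0.0,
            r=0,
            n=n,
            row_mean=row_mean,
            base_mean=base_mean,
            centered=center,
        )
    frac = s**2 / total
    cum = np.cumsum(frac)
    r = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    r = min(r, s.size)
    directions = Vt[:r].copy()
    for j in range(r):
        peak = np.argmax(np.abs(directions[j]))
        if directions[j, peak] < 0:
            directions[j] = -directions[j]
    scores = Vc @ directions.T
    return TangentPCAModel(
        directions=directions,
        singular_values=s[:r].copy(),
        scores=scores,
        variance_fractions=frac[:r].copy(),
        cumulative_variance=cum[:r].copy(),
        total_variance=total,
        r=r,
        n=n,
        row_mean=row_mean,
        base_mean=base_mean,
        centered=center,
    )


def fit(
    mean: SRTFunction,
    hs: Sequence[SRTFunction],
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    *,
    center: bool = True,
) -> TangentPCAModel:
    """Convenience: tangent matrix at ``mean`` followed by the PCA fit."""
    V = tangent_matrix(mean, hs)
    return fit_tangent_pca(V, variance_threshold, base_mean=mean, center=center)


def project(model: TangentPCAModel, h_new: SRTFunction) -> np.ndarray:
    """Score vector (length r) of a new SRT under a fitted model."""
    if model.base_mean is None:
        raise ValueError("model has no base mean recorded; fit with base_mean")
    mean = model.base_mean
    if h_new.values.shape != mean.values.shape or not np.array_equal(h_new.grid, mean.grid):
        raise ValueError("grid mismatch between model and new SRT")
    v = log_map(mean, h_new).values * model.quad_sqrt
    return (v - model.row_mean) @ model.directions.T


def principal_path(
    model: TangentPCAModel,
    component: int,
    sd_multiples: Sequence[float] = (-2.0, -1.0, 0.0, 1.0, 2.0),
) -> list[DensityFunction]:
    """Densities along a principal geodesic through the Karcher mean.

    For multiple k, returns inverse_srt(exp_mean(k * sd_c * u_c)) where
    sd_c = sigma_c / sqrt(n - 1) is the component's score standard
    deviation and u_c the unit tangent direction; k = 0 returns the
    Karcher-mean density exactly.  ``component`` is 1-based (PC1 = 1).
    """
    if model.base_mean is None:
        raise ValueError("model has no base mean recorded; fit with base_mean")
    if not 1 <= component <= model.r:
        raise ValueError(f"component must be in 1..{model.r}, got {component}")
    mean = model.base_mean
    sd = float(model.singular_values[component - 1]) / np.sqrt(model.n - 1)
    direction = model.directions[component - 1] / model.quad_sqrt
    out = []
    for k in sd_multiples:
        if k == 0:
            out.append(inverse_srt(mean))
        else:
            v = TangentVector(mean, k * sd * direction)
            out.append(inverse_srt(exp_map(mean, v)))
    return out
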