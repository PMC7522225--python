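"""Fisher-Rao geometry of probability densities via the square-root transform.

A density ``f`` on [0, 1] is represented by its values on a shared uniform
grid.  Its square-root transform (SRT) ``h = sqrt(f)`` lies on the positive
orthant of the unit sphere in L2([0, 1]), where the Fisher-Rao metric reduces
to the standard L2 metric.  On the sphere everything has a closed form:

* geodesic distance    ``d(h1, h2) = arccos <h1, h2>``
* exponential map      ``exp_h(v)  = cos(|v|) h + sin(|v|) v / |v|``
* inverse exponential  ``log_h1(h2) = theta (h2 - cos(theta) h1) / sin(theta)``

with ``<., .>`` the L2 inner product, approximated everywhere by trapezoidal
quadrature on the shared grid.  The Karcher (Frechet) mean of a sample of
SRTs minimises the sum of squared geodesic distances and is computed by
gradient descent in the tangent space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np

__all__ = [
    "DensityFunction",
    "SRTFunction",
    "TangentVector",
    "KarcherMeanResult",
    "unit_grid",
    "trapezoid_weights",
    "srt",
    "inverse_srt",
    "l2_inner",
    "l2_norm",
    "geodesic_distance",
    "exp_map",
    "log_map",
    "karcher_mean",
    "karcher_variance",
]

DEFAULT_GRID_SIZE = 512

#: below this angle, log_map returns the zero-vector limit
_THETA_FLOOR = 1e-9


def unit_grid(m: int) -> np.ndarray:
    """``m`` equally spaced points spanning [0, 1]."""
    if m < 2:
        raise ValueError(f"grid needs at least 2 points, got {m}")
    return np.linspace(0.0, 1.0, m)


def trapezoid_weights(m: int) -> np.ndarray:
    """Quadrature weights w with sum(w * g) = trapezoidal integral of g."""
    if m < 2:
        raise ValueError(f"grid needs at least 2 points, got {m}")
    dx = 1.0 / (m - 1)
    w = np.full(m, dx)
    w[0] = w[-1] = dx / 2.0
    return w


def _as_grid_values(obj: Any) -> tuple[np.ndarray | None, np.ndarray]:
    """Return (grid or None, values) for grid functions or bare arrays."""
    if hasattr(obj, "values") and hasattr(obj, "grid"):
        return obj.grid, obj.values
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 1:
        raise ValueError("grid functions must be one-dimensional")
    return None, arr


def _check_same_grid(g1: np.ndarray | None, g2: np.ndarray | None) -> None:
    if g1 is None or g2 is None:
        return
    if g1.shape != g2.shape or not np.array_equal(g1, g2):
        raise ValueError("grid mismatch between operands")


@dataclass
class DensityFunction:
    """A probability density evaluated on a uniform grid over [0, 1].

    ``transform`` records the affine micrometre -> [0, 1] map used to build
    the density (a :class:`~retdens.density_estimation.DomainTransform`),
    so quantities such as tail mass above a thickness threshold can be
    recovered on the original scale.
    """

    grid: np.ndarray
    values: np.ndarray
    transform: Any = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape or self.grid.ndim != 1:
            raise ValueError("grid and values must be 1-d arrays of equal length")
        if np.any(self.values < -1e-10):
            raise ValueError("density values must be nonnegative")
        self.values = np.maximum(self.values, 0.0)
        mass = float(np.sum(trapezoid_weights(self.grid.size) * self.values))
        if abs(mass - 1.0) > 1e-8:
            raise ValueError(f"density does not integrate to 1 (got {mass!r})")

    @property
    def mass(self) -> float:
        return float(np.sum(trapezoid_weights(self.grid.size) * self.values))


@dataclass
class SRTFunction:
    """Square-root transform h = sqrt(f); a point on the unit Hilbert sphere."""

    grid: np.ndarray
    values: np.ndarray
    transform: Any = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape or self.grid.ndim != 1:
            raise ValueError("grid and values must be 1-d arrays of equal length")
        sq = float(np.sum(trapezoid_weights(self.grid.size) * self.values**2))
        if abs(sq - 1.0) > 1e-8:
            raise ValueError(f"SRT is not unit-norm (||h||^2 = {sq!r})")


@dataclass
class TangentVector:
    """A tangent vector at ``base``: orthogonal to it in L2."""

    base: SRTFunction
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.base.values.shape:
            raise ValueError("tangent values must share the base grid")
        w = trapezoid_weights(self.values.size)
        ip = float(np.sum(w * self.base.values * self.values))
        if abs(ip) > 1e-8:
            raise ValueError(f"tangent vector not orthogonal to base (<h,v> = {ip!r})")

    @property
    def norm(self) -> float:
        w = trapezoid_weights(self.values.size)
        return float(np.sqrt(np.sum(w * self.values**2)))


@dataclass
class KarcherMeanResult:
    mean: SRTFunction
    variance: float
    iterations: int
    final_gradient_norm: float
    converged: bool

    @property
    def mean_density(self) -> DensityFunction:
        """The average density f-bar = h-bar^2."""
        return inverse_srt(self.mean)


def srt(f: DensityFunction) -> SRTFunction:
    """Square-root transform of a density; errors on negative values."""
    if np.any(f.values < 0):
        raise ValueError("density values must be nonnegative")
    return SRTFunction(f.grid, np.sqrt(f.values), transform=f.transform)


def inverse_srt(h: SRTFunction) -> DensityFunction:
    """Inverse transform f = h^2 (unique on the positive orthant)."""
    return DensityFunction(h.grid, h.values**2, transform=h.transform)


def l2_inner(g1: Any, g2: Any) -> float:
    """Trapezoidal approximation of the L2 inner product on [0, 1]."""
    grid1, v1 = _as_grid_values(g1)
    grid2, v2 = _as_grid_values(g2)
    _check_same_grid(grid1, grid2)
    if v1.shape != v2.shape:
        raise ValueError("grid mismatch between operands")
    # product formed first so the quadrature sum is exactly symmetric
    return float(np.sum(trapezoid_weights(v1.size) * (v1 * v2)))


def l2_norm(g: Any) -> float:
    return float(np.sqrt(max(l2_inner(g, g), 0.0)))


def geodesic_distance(h1: SRTFunction, h2: SRTFunction, *, norm_tol: float = 1e-6) -> float:
    """Arc length between two SRTs on the unit sphere, in [0, pi]."""
    _check_same_grid(h1.grid, h2.grid)
    for h in (h1, h2):
        if abs(l2_inner(h, h) - 1.0) > norm_tol:
            raise ValueError("geodesic_distance requires unit-norm SRT inputs")
    if np.array_equal(h1.values, h2.values):
        return 0.0  # avoid arccos round-off at the diagonal
    ip = np.clip(l2_inner(h1, h2), -1.0, 1.0)
    return float(np.arccos(ip))


def exp_map(h: SRTFunction, v: TangentVector) -> SRTFunction:
    """Shoot the geodesic from ``h`` with initial velocity ``v`` for unit time."""
    if v.base is not h and not np.array_equal(v.base.values, h.values):
        raise ValueError("tangent vector is not based at the given SRT")
    nv = v.norm
    if nv < 1e-12:
        return SRTFunction(h.grid, h.values.copy(), transform=h.transform)
    out = np.cos(nv) * h.values + np.sin(nv) * v.values / nv
    return SRTFunction(h.grid, out, transform=h.transform)


def log_map(h1: SRTFunction, h2: SRTFunction) -> TangentVector:
    """Inverse exponential map: the tangent vector at ``h1`` pointing to ``h2``.

    Returns the zero vector in the theta -> 0 limit; near-antipodal pairs
    (theta -> pi) raise, though they cannot occur for nonnegative SRTs.
    """
    _check_same_grid(h1.grid, h2.grid)
    theta = geodesic_distance(h1, h2)
    if theta < _THETA_FLOOR:
        return TangentVector(h1, np.zeros_like(h1.values))
    if theta > np.pi - 1e-6:
        raise FloatingPointError("log_map undefined for near-antipodal SRTs")
    vals = theta * (h2.values - np.cos(theta) * h1.values) / np.sin(theta)
    return TangentVector(h1, vals)


# ---------------------------------------------------------------------------
# Karcher mean
# ---------------------------------------------------------------------------

def _log_rows(mu: np.ndarray, H: np.ndarray, wq: np.ndarray) -> np.ndarray:
    """Stacked log_mu(h_i) for rows of H; all arrays raw, no validation."""
    dots = np.clip(H @ (mu * wq), -1.0, 1.0)
    theta = np.arccos(dots)
    small = theta < _THETA_FLOOR
    coef = np.where(small, 1.0, theta / np.sin(np.where(small, 1.0, theta)))
    return coef[:, None] * (H - dots[:, None] * mu[None, :])


def _karcher_stack(
    H: np.ndarray,
    W: np.ndarray,
    wq: np.ndarray,
    *,
    tol: float = 1e-6,
    step: float = 0.5,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Batched Karcher means on the sphere.

    ``H`` is (n, m) of SRT values; each row b of ``W`` (B, n) holds
    nonnegative weights summing to 1 selecting/weighting the sample for
    batch member b.  Returns (means (B, m), iterations, gradient norms,
    converged flags).  Iterate: mu <- exp_mu(step * vbar) with vbar the
    weighted average of log_mu(h_i), from the normalised extrinsic mean.
    """
    B = W.shape[0]
    mu = W @ H
    mu /= np.sqrt(((mu**2) * wq).sum(axis=1, keepdims=True))
    converged = np.zeros(B, dtype=bool)
    iters = np.zeros(B, dtype=int)
    gnorm = np.full(B, np.inf)
    for it in range(1, max_iter + 1):
        dots = np.clip((mu * wq) @ H.T, -1.0, 1.0)  # (B, n) of cos(theta)
        theta = np.arccos(dots)
        small = theta < _THETA_FLOOR
        coef = np.where(small, 1.0, theta / np.sin(np.where(small, 1.0, theta)))
        WC = W * coef
        vbar = WC @ H - (WC * dots).sum(axis=1, keepdims=True) * mu
        g = np.sqrt(((vbar**2) * wq).sum(axis=1))
        active = ~converged
        iters[active] = it
        gnorm[active] = g[active]
        newly = active & (g < tol)
        converged |= newly
        active = ~converged
        if not active.any():
            break
        ga = g[active][:, None]
        upd = np.cos(step * ga) * mu[active] + np.sin(step * ga) * (vbar[active] / ga)
        upd /= np.sqrt(((upd**2) * wq).sum(axis=1, keepdims=True))
        mu[active] = upd
    return mu, iters, gnorm, converged


def _stack_srts(hs: Sequence[SRTFunction]) -> tuple[np.ndarray, np.ndarray]:
    grid = hs[0].grid
    for h in hs[1:]:
        _check_same_grid(grid, h.grid)
        if h.values.shape != grid.shape:
            raise ValueError("grid mismatch between SRTs")
    return grid, np.stack([h.values for h in hs])


def karcher_mean(
    hs: Sequence[SRTFunction],
    *,
    tol: float = 1e-6,
    max_iter: int = 100,
    step: float = 0.5,
) -> KarcherMeanResult:
    """Karcher (Frechet) mean of a sample of SRTs by tangent gradient descent.

    Initialised at the normalised pointwise average (always in the positive
    orthant); stops when the gradient norm drops below ``tol``.  A run that
    exhausts ``max_iter`` reports ``converged=False`` rather than raising.
    """
    if len(hs) == 0:
        raise ValueError("karcher_mean needs at least one SRT")
    grid, H = _stack_srts(hs)
    wq = trapezoid_weights(grid.size)
    W = np.full((1, len(hs)), 1.0 / len(hs))
    mu, iters, gnorm, conv = _karcher_stack(H, W, wq, tol=tol, step=step, max_iter=max_iter)
    mean = SRTFunction(grid, mu[0], transform=hs[0].transform)
    return KarcherMeanResult(
        mean=mean,
        variance=karcher_variance(mean, hs),
        iterations=int(iters[0]),
        final_gradient_norm=float(gnorm[0]),
        converged=bool(conv[0]),
    )


def karcher_variance(mean: SRTFunction, hs: Sequence[SRTFunction]) -> float:
    """Sum of squared geodesic distances from ``mean`` to each sample SRT."""
    return float(sum(geodesic_distance(mean, h) ** 2 for h in hs))
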