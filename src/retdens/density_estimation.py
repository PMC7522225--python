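"""From pixel-thickness samples to densities on the shared unit-interval grid.

All subjects in one comparison share a single affine map from micrometres to
[0, 1] (pooled min/max with a small pad), so between-subject location
differences survive the normalisation and the whole analysis is invariant to
consistent re-scaling or shifting of the raw thickness values.  Each subject's
density is a Gaussian kernel density estimate of the unit-interval sample,
evaluated on the shared grid and renormalised to unit trapezoidal mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterable, Sequence

import numpy as np

from .sphere_geometry import DEFAULT_GRID_SIZE, DensityFunction, trapezoid_weights, unit_grid

__all__ = [
    "DomainTransform",
    "pooled_domain_transform",
    "silverman_bandwidth",
    "estimate_pdf",
    "tail_mass_above",
]


@dataclass(frozen=True)
class DomainTransform:
    """Affine map x = (t - a) / b from thickness (um) to the unit interval."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("DomainTransform scale b must be positive")

    def to_unit(self, t: Any) -> np.ndarray:
        return (np.asarray(t, dtype=float) - self.a) / self.b

    def to_thickness(self, x: Any) -> np.ndarray:
        return self.a + self.b * np.asarray(x, dtype=float)


def _sample_values(sample: Any) -> np.ndarray:
    vals = sample.values if hasattr(sample, "values") else sample
    return np.asarray(vals, dtype=float).ravel()


def pooled_domain_transform(
    samples: Iterable[Any], *, pad_fraction: float = 0.01
) -> DomainTransform:
    """Shared um -> [0, 1] transform from the pooled range of all samples.

    ``a = min - pad`` and ``b = range + 2 pad`` with ``pad`` a fixed fraction
    of the pooled range (1 um for a degenerate, zero-range pool).  The pad
    keeps every sample strictly inside (0, 1), away from the boundary of the
    density manifold where the square-root geometry degenerates.
    """
    pooled_min = np.inf
    pooled_max = -np.inf
    any_values = False
    for s in samples:
        v = _sample_values(s)
        if v.size == 0:
            continue
        any_values = True
        pooled_min = min(pooled_min, float(v.min()))
        pooled_max = max(pooled_max, float(v.max()))
    if not any_values:
        raise ValueError("pooled_domain_transform requires at least one non-empty sample")
    rng = pooled_max - pooled_min
    pad = pad_fraction * rng if rng > 0 else 1.0
    return DomainTransform(a=pooled_min - pad, b=rng + 2.0 * pad)


def silverman_bandwidth(x: np.ndarray) -> float:
    """Normal-reference (Silverman) rule 0.9 min(sd, IQR/1.349) n^(-1/5).

    Falls back to 0.01 (on the unit scale) for degenerate samples whose
    spread is zero, so a constant sample still yields a proper density.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return 0.01
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75.0, 25.0])
    iqr = float(q75 - q25)
    spreads = [s for s in (sd, iqr / 1.349) if s > 0]
    if not spreads:
        return 0.01
    return 0.9 * min(spreads) * n ** (-1.0 / 5.0)


def estimate_pdf(
    sample: Any,
    transform: DomainTransform,
    grid_size: int = DEFAULT_GRID_SIZE,
    bandwidth: float | None = None,
) -> DensityFunction:
    """Gaussian KDE of the unit-interval sample on the shared uniform grid.

    The raw KDE is renormalised so the trapezoidal integral over [0, 1] is
    exactly 1 (plain KDE leaks a little mass outside the interval; with the
    pooled-transform pad that leak is negligible and renormalisation removes
    the rest).  Deterministic: no randomness is involved.
    """
    vals = _sample_values(sample)
    if vals.size == 0:
        raise ValueError("estimate_pdf requires a non-empty sample")
    if grid_size < 16:
        raise ValueError(f"grid_size must be >= 16, got {grid_size}")
    x = transform.to_unit(vals)
    if bandwidth is None:
        bandwidth = silverman_bandwidth(x)
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    grid = unit_grid(grid_size)
    f = np.zeros(grid_size)
    # chunked so the (chunk, grid) kernel matrix stays small
    chunk = max(1, int(4_000_000 / grid_size))
    inv = 1.0 / bandwidth
    for start in range(0, x.size, chunk):
        xi = x[start : start + chunk, None]
        z = (grid[None, :] - xi) * inv
        f += np.exp(-0.5 * z * z).sum(axis=0)
    f *= inv / (np.sqrt(2.0 * np.pi) * x.size)
    f /= np.sum(trapezoid_weights(grid_size) * f)
    return DensityFunction(grid, f, transform=transform)


def tail_mass_above(density: DensityFunction, thickness: float = 50.0) -> float:
    """Probability mass of the density above a thickness threshold in um.

    Uses the recorded domain transform to place the threshold on [0, 1] and
    integrates the trapezoid-interpolated density from there to 1.
    """
    if density.transform is None:
        raise ValueError("density has no recorded domain transform")
    x0 = float(density.transform.to_unit(thickness))
    if x0 <= 0.0:
        return 1.0
    if x0 >= 1.0:
        return 0.0
    x, f = density.grid, density.values
    keep = x > x0
    xs = np.concatenate(([x0], x[keep]))
    fs = np.concatenate(([np.interp(x0, x, f)], f[keep]))
    return float(np.trapezoid(fs, xs))
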