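"""Decode thickness heatmaps and extract ETDRS-grid pixel samples.

The analysis consumes per-subject, per-layer maps of retinal thickness in
micrometres.  Clinical exports encode these as RGB heatmaps with a known
colour bar; :func:`decode_thickness_image` inverts the encoding by nearest
colour.  An ETDRS grid (concentric rings of 1, 3 and 6 mm diameter centred
on the fovea) selects the macular region; all non-missing pixels inside the
full 6 mm disc form one pooled, unordered thickness sample per subject.
Left-eye maps are flipped horizontally so anatomy lines up across eyes --
a no-op for the unordered pixel sample, retained for plotting fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "OUTSIDE",
    "CENTER_DISC",
    "INNER_RING",
    "OUTER_RING",
    "ThicknessMap",
    "Colorbar",
    "RegionMask",
    "PixelSample",
    "build_etdrs_mask",
    "decode_thickness_image",
    "orient_map",
    "extract_pixels",
]

OUTSIDE = 0
CENTER_DISC = 1
INNER_RING = 2
OUTER_RING = 3

#: ETDRS ring diameters in mm
ETDRS_DIAMETERS_MM = (1.0, 3.0, 6.0)


@dataclass
class ThicknessMap:
    """2-d grid of thickness values (um) with a missing-pixel mask.

    ``center`` is the fovea position in 0-based (row, col) pixel coordinates
    (row 0 at the top); ``pixel_spacing`` is mm per pixel.
    """

    values: np.ndarray
    missing: np.ndarray
    pixel_spacing: float
    center: tuple[float, float]
    laterality: str = "right"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.values.ndim != 2 or self.values.shape != self.missing.shape:
            raise ValueError("values and missing must be 2-d arrays of equal shape")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.laterality not in ("left", "right"):
            raise ValueError(f"laterality must be 'left' or 'right', got {self.laterality!r}")
        ok = self.values[~self.missing]
        if ok.size and (not np.all(np.isfinite(ok)) or np.any(ok < 0)):
            raise ValueError("non-missing thickness values must be finite and >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class Colorbar:
    """Ordered (thickness value, RGB colour) entries plus a background colour."""

    values: np.ndarray
    colors: np.ndarray
    background: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.colors = np.asarray(self.colors, dtype=np.uint8)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("colorbar must have at least one entry")
        if self.colors.shape != (self.values.size, 3):
            raise ValueError("colors must be (n_entries, 3)")
        if np.any(np.diff(self.values) <= 0):
            raise ValueError("colorbar values must be strictly increasing")
        palette = {tuple(c) for c in self.colors.tolist()}
        if len(palette) != self.values.size:
            raise ValueError("colorbar colors must be distinct")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class RegionMask:
    """Per-pixel ETDRS region labels (outside / center disc / inner / outer ring)."""

    labels: np.ndarray
    pixel_spacing: float
    center: tuple[float, float]

    @property
    def in_grid(self) -> np.ndarray:
        """Boolean mask of all pixels inside the full 6 mm disc."""
        return self.labels != OUTSIDE


@dataclass
class PixelSample:
    """Unordered non-missing thickness values (um) from inside the ETDRS grid."""

    values: np.ndarray
    subject_id: str = ""
    layer: str = ""
    n_excluded_missing: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size and (np.any(~np.isfinite(self.values)) or np.any(self.values < 0)):
            raise ValueError("pixel sample values must be finite and >= 0")

    def __len__(self) -> int:
        return self.values.size


def build_etdrs_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    pixel_spacing: float,
    diameters_mm: Sequence[float] = ETDRS_DIAMETERS_MM,
) -> RegionMask:
    """Label each pixel by the ETDRS annulus containing its centre.

    Membership uses the Euclidean distance of the pixel centre to the fovea
    centre; a pixel at >= 3 mm (the 6 mm diameter radius) is outside.
    """
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be positive")
    r1, r2, r3 = (d / 2.0 for d in diameters_mm)
    rows = (np.arange(shape[0]) - center[0]) * pixel_spacing
    cols = (np.arange(shape[1]) - center[1]) * pixel_spacing
    dist = np.hypot(rows[:, None], cols[None, :])
    labels = np.full(shape, OUTSIDE, dtype=np.int8)
    labels[dist < r3] = OUTER_RING
    labels[dist < r2] = INNER_RING
    labels[dist < r1] = CENTER_DISC
    return RegionMask(labels=labels, pixel_spacing=pixel_spacing, center=tuple(center))


def decode_thickness_image(
    rgb: np.ndarray,
    colorbar: Colorbar,
    pixel_spacing: float = 1.0,
    center: tuple[float, float] | None = None,
    laterality: str = "right",
    tolerance: float | None = None,
) -> ThicknessMap:
    """Invert a heatmap: each pixel gets the thickness of its nearest colour.

    Colour distance is squared Euclidean in 8-bit RGB.  Pixels whose nearest
    colour is the background, or whose distance to every entry exceeds
    ``tolerance`` (default 3x the minimum inter-entry distance), are flagged
    missing.  Ties go to the lower-valued entry.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3 or rgb.size == 0:
        raise ValueError("expected a non-empty (H, W, 3) RGB image")
    if len(colorbar) == 0:
        raise ValueError("colorbar must be non-empty")
    entries = colorbar.colors.astype(float)
    if len(colorbar) > 1:
        diff = entries[:, None, :] - entries[None, :, :]
        d2 = (diff**2).sum(-1)
        min_inter = float(d2[~np.eye(len(colorbar), dtype=bool)].min())
    else:
        min_inter = 3.0 * 255.0**2
    if tolerance is None:
        tolerance = 3.0 * min_inter
    cand = np.vstack([entries, np.asarray(colorbar.background, dtype=float)[None, :]])
    P = rgb.reshape(-1, 3).astype(float)
    # squared distances via |p|^2 - 2 p.c + |c|^2; argmin keeps the first
    # (lowest-valued) entry on exact ties
    d2 = (P**2).sum(1)[:, None] - 2.0 * (P @ cand.T) + (cand**2).sum(1)[None, :]
    nearest = d2.argmin(axis=1)
    mind2 = d2[np.arange(P.shape[0]), nearest]
    missing = (nearest == len(colorbar)) | (mind2 > tolerance)
    values = colorbar.values[np.minimum(nearest, len(colorbar) - 1)]
    values[missing] = 0.0
    h, w = rgb.shape[:2]
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    return ThicknessMap(
        values=values.reshape(h, w),
        missing=missing.reshape(h, w),
        pixel_spacing=pixel_spacing,
        center=center,
        laterality=laterality,
    )


def orient_map(tmap: ThicknessMap) -> ThicknessMap:
    """Mirror left-eye maps about the vertical axis; right-eye maps pass through.

    Column ``c`` maps to ``ncols - 1 - c`` (the fovea centre column included),
    so applying the operation twice restores the original map.
    """
    if tmap.laterality == "right":
        return tmap
    ncols = tmap.shape[1]
    return ThicknessMap(
        values=tmap.values[:, ::-1].copy(),
        missing=tmap.missing[:, ::-1].copy(),
        pixel_spacing=tmap.pixel_spacing,
        center=(tmap.center[0], ncols - 1 - tmap.center[1]),
        laterality=tmap.laterality,
    )


def extract_pixels(
    tmap: ThicknessMap,
    mask: RegionMask,
    subject_id: str = "",
    layer: str = "",
) -> PixelSample:
    """All non-missing thickness values inside the 6 mm ETDRS disc."""
    if mask.labels.shape != tmap.shape:
        raise ValueError("map and region mask shapes do not agree")
    in_grid = mask.in_grid
    keep = in_grid & ~tmap.missing
    return PixelSample(
        values=tmap.values[keep],
        subject_id=subject_id,
        layer=layer,
        n_excluded_missing=int((in_grid & tmap.missing).sum()),
    )
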