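"""Membrane fluorescence patch quantification.

Given a grayscale image and a cell-outline polygon, the perimeter is
resampled at equidistant points (2 px apart by default), a short normal
(3 px) is drawn at each point and the maximum intensity along it taken as
that point's membrane value.  The patch threshold is the cytosol mean plus
three standard deviations; the patch fraction is the fraction of perimeter
points strictly above it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import ndimage
from shapely.geometry import LinearRing
from skimage.draw import polygon as draw_polygon

__all__ = [
    "CellOutline",
    "PatchResult",
    "resample_perimeter",
    "sample_normals",
    "cytosol_stats",
    "patch_fraction",
    "quantify_cell",
]


@dataclass(frozen=True)
class CellOutline:
    """Closed polygon of (x, y) pixel coordinates, counter-clockwise.

    Pixel convention: origin top-left, x rightward, y downward.  The polygon
    is implicitly closed (last vertex connects back to the first).
    """

    vertices: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array of (x, y)")
        if np.array_equal(v[0], v[-1]):
            v = v[:-1]  # drop explicit closing vertex
        if len(v) < 3:
            raise ValueError("outline needs at least 3 distinct vertices")
        ring = LinearRing(v)
        if not ring.is_valid:
            raise ValueError("outline polygon is self-intersecting or degenerate")
        if not ring.is_ccw:
            v = v[::-1].copy()
        object.__setattr__(self, "vertices", v)

    @property
    def ring(self) -> LinearRing:
        return LinearRing(self.vertices)

    @property
    def perimeter(self) -> float:
        return self.ring.length

    @property
    def centroid(self) -> np.ndarray:
        from shapely.geometry import Polygon

        c = Polygon(self.vertices).centroid
        return np.array([c.x, c.y])


@dataclass(frozen=True)
class PatchResult:
    perimeter_points: np.ndarray
    membrane_values: np.ndarray  # NaN where all normal samples were off-image
    cytosol_mean: float
    cytosol_sd: float
    threshold: float
    patch_fraction: float

    def __post_init__(self):
        if not 0 <= self.patch_fraction <= 1:
            raise ValueError("patch fraction must lie in [0, 1]")
        if self.threshold < self.cytosol_mean:
            raise ValueError("threshold below cytosol mean")
        if len(self.membrane_values) != len(self.perimeter_points):
            raise ValueError("one membrane value per perimeter point required")

    @property
    def n_points(self) -> int:
        return int(np.sum(~np.isnan(self.membrane_values)))


def resample_perimeter(outline: CellOutline, spacing: float = 2.0) -> np.ndarray:
    """Equidistant points on the polygon at arc-length multiples of
    ``spacing`` starting from vertex 0; floor(perimeter / spacing) points."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    ring = outline.ring
    length = ring.length
    if spacing > length:
        raise ValueError(f"spacing {spacing} exceeds perimeter {length:.1f}")
    n = int(length // spacing)
    pts = [ring.interpolate(k * spacing) for k in range(n)]
    return np.array([[p.x, p.y] for p in pts])


def sample_normals(
    image: np.ndarray,
    points: np.ndarray,
    outline: CellOutline,
    normal_len: int = 3,
    direction: Literal["centered", "inward", "outward"] = "centered",
) -> np.ndarray:
    """Max intensity along a short normal at each perimeter point.

    The normal direction at a point is estimated from its neighbouring
    perimeter points and oriented away from the outline centroid.  Sampling
    is nearest-pixel; samples off the image are ignored, and a point whose
    samples are all off-image gets NaN.
    """
    if normal_len < 1:
        raise ValueError("normal length must be >= 1")
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    n = len(points)
    if n == 0:
        raise ValueError("no perimeter points to sample")
    centroid = outline.centroid

    if direction == "centered":
        offsets = np.arange(normal_len) - (normal_len - 1) // 2
    elif direction == "inward":
        offsets = np.arange(-(normal_len - 1), 1)
    elif direction == "outward":
        offsets = np.arange(normal_len)
    else:
        raise ValueError(f"unknown direction {direction!r}")

    values = np.full(n, np.nan)
    for k in range(n):
        tangent = points[(k + 1) % n] - points[(k - 1) % n]
        norm = np.hypot(*tangent)
        if norm == 0:
            normal = points[k] - centroid
            norm = np.hypot(*normal)
            if norm == 0:
                continue
        else:
            normal = np.array([tangent[1], -tangent[0]])
        normal = normal / np.hypot(*normal)
        if np.dot(normal, points[k] - centroid) < 0:
            normal = -normal
        best = np.nan
        for o in offsets:
            x = int(round(points[k, 0] + o * normal[0]))
            y = int(round(points[k, 1] + o * normal[1]))
            if 0 <= x < w and 0 <= y < h:
                val = image[y, x]
                if np.isnan(best) or val > best:
                    best = val
        values[k] = best
    return values


def _interior_mask(image_shape: tuple[int, int], outline: CellOutline) -> np.ndarray:
    rr, cc = draw_polygon(outline.vertices[:, 1], outline.vertices[:, 0], image_shape)
    mask = np.zeros(image_shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def cytosol_stats(
    image: np.ndarray, outline: CellOutline, margin: float = 3.0
) -> tuple[float, float]:
    """Mean and population standard deviation over interior pixels farther
    than ``margin`` from the outline, so that membrane pixels within reach of
    the normals never contaminate the cytosol statistics."""
    image = np.asarray(image, dtype=float)
    mask = _interior_mask(image.shape, outline)
    dist = ndimage.distance_transform_edt(mask)
    core = dist > margin
    if not core.any():
        raise ValueError("no interior pixels left after erosion — cell too small")
    vals = image[core]
    return float(vals.mean()), float(vals.std(ddof=0))


def patch_fraction(
    membrane_values: np.ndarray,
    cytosol_mean: float,
    cytosol_sd: float,
    perimeter_points: Optional[np.ndarray] = None,
    sd_multiplier: float = 3.0,
) -> PatchResult:
    """Fraction of non-missing membrane values strictly above
    cytosol_mean + sd_multiplier * cytosol_sd."""
    membrane_values = np.asarray(membrane_values, dtype=float)
    valid = ~np.isnan(membrane_values)
    if not valid.any():
        raise ValueError("no valid membrane values")
    threshold = cytosol_mean + sd_multiplier * cytosol_sd
    frac = float(np.sum(membrane_values[valid] > threshold) / valid.sum())
    if perimeter_points is None:
        perimeter_points = np.full((len(membrane_values), 2), np.nan)
    return PatchResult(
        perimeter_points=np.asarray(perimeter_points, dtype=float),
        membrane_values=membrane_values,
        cytosol_mean=float(cytosol_mean),
        cytosol_sd=float(cytosol_sd),
        threshold=float(threshold),
        patch_fraction=frac,
    )


def quantify_cell(
    image: np.ndarray,
    outline: CellOutline,
    spacing: float = 2.0,
    normal_len: int = 3,
    margin: float = 3.0,
    sd_multiplier: float = 3.0,
    direction: Literal["centered", "inward", "outward"] = "centered",
) -> PatchResult:
    """Full per-cell quantification: resample perimeter, sample normals,
    cytosol statistics, threshold, patch fraction."""
    points = resample_perimeter(outline, spacing)
    values = sample_normals(image, points, outline, normal_len, direction)
    mean, sd = cytosol_stats(image, outline, margin)
    return patch_fraction(values, mean, sd, perimeter_points=points, sd_multiplier=sd_multiplier)
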