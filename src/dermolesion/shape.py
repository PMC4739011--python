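"""Geometric descriptors of a binary lesion mask.

Eight descriptors summarizing outline irregularity, all normalized to be
scale-, rotation- and translation-invariant: maximal diameter, equivalent
(same-area circle) diameter, variance of the radial distance distribution,
rectangularity, elongation, moment-ellipse eccentricity, Haralick's
compactness, and Bribiesca's normalized discrete compactness.

Conventions: boundary pixels are foreground pixels with at least one
background 4-neighbor; diameters are measured between pixel *centers*;
rectangularity and elongation use the minimum-area *oriented* bounding
rectangle of the pixel-cell hull (each pixel treated as a unit square), so
an axis-aligned k x k square scores rectangularity exactly 1.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage.measure import regionprops

from .segment import LesionMask

#: cap returned by haralick_compactness when the boundary radii have zero spread
HARALICK_CAP = 1e6


def _mask_array(mask) -> np.ndarray:
    m = mask.pixels if isinstance(mask, LesionMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    return m


def boundary_pixels(mask) -> np.ndarray:
    """(N, 2) array of inner-boundary pixel coordinates (row, col).

    A foreground pixel is boundary if any of its 4-neighbors is background
    (image edges count as background).
    """
    m = _mask_array(mask)
    interior = ndimage.binary_erosion(m, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    return np.argwhere(m & ~interior)


def _center_hull_points(m: np.ndarray) -> np.ndarray:
    pts = np.argwhere(m).astype(float)
    if len(pts) < 3:
        return pts
    try:
        hull = ConvexHull(pts)
        return pts[hull.vertices]
    except Exception:  # collinear point sets
        return pts


def _cell_corner_hull(m: np.ndarray) -> np.ndarray:
    """Convex hull vertices of the union of unit pixel cells."""
    pts = np.argwhere(m).astype(float)
    corners = np.concatenate(
        [pts + d for d in ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))]
    )
    hull = ConvexHull(corners)
    return corners[hull.vertices]


def _min_area_rect(hull_pts: np.ndarray) -> tuple[float, float]:
    """Side lengths (long, short) of the minimum-area oriented bounding
    rectangle, by rotating calipers over hull edges."""
    n = len(hull_pts)
    if n == 1:
        return 0.0, 0.0
    best = None
    for i in range(n):
        edge = hull_pts[(i + 1) % n] - hull_pts[i]
        norm = np.hypot(*edge)
        if norm == 0:
            continue
        u = edge / norm
        v = np.array([-u[1], u[0]])
        proj_u = hull_pts @ u
        proj_v = hull_pts @ v
        du = proj_u.max() - proj_u.min()
        dv = proj_v.max() - proj_v.min()
        if best is None or du * dv < best[0]:
            best = (du * dv, max(du, dv), min(du, dv))
    if best is None:  # all points coincident
        return 0.0, 0.0
    return best[1], best[2]


def max_diameter(mask) -> float:
    """Largest Euclidean distance between two foreground pixel centers."""
    m = _mask_array(mask)
    hull_pts = _center_hull_points(m)
    if len(hull_pts) == 1:
        return 0.0
    d2 = ((hull_pts[:, None, :] - hull_pts[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max()))


def equivalent_diameter(mask) -> float:
    """Diameter of the circle with the same area: sqrt(4 * Area / pi)."""
    m = _mask_array(mask)
    return float(np.sqrt(4.0 * m.sum() / np.pi))


def radial_variance(mask) -> float:
    """Normalized variance of the boundary-to-centroid distance.

    ``(1/|B|) * sum_B (d - dbar)^2 / dbar^2`` — near 0 for a disk, large
    for star-shaped or elongated outlines. Defined as 0 for a single pixel.
    """
    m = _mask_array(mask)
    b = boundary_pixels(m)
    centroid = np.argwhere(m).mean(axis=0)
    d = np.hypot(*(b - centroid).T)
    dbar = d.mean()
    if dbar == 0:
        return 0.0
    return float(np.mean((d - dbar) ** 2) / dbar**2)


def rectangularity(mask) -> float:
    """Area over the area of the minimum oriented bounding rectangle."""
    m = _mask_array(mask)
    long_side, short_side = _min_area_rect(_cell_corner_hull(m))
    if long_side * short_side == 0:
        return 1.0
    return float(m.sum() / (long_side * short_side))


def elongation(mask) -> float:
    """Aspect ratio (long/short side) of the oriented bounding rectangle."""
    m = _mask_array(mask)
    long_side, short_side = _min_area_rect(_cell_corner_hull(m))
    if short_side == 0:
        return 1.0
    return float(long_side / short_side)


def eccentricity(mask) -> float:
    """Eccentricity of the second-central-moment equivalent ellipse, in [0, 1]."""
    m = _mask_array(mask)
    if m.sum() < 2:
        return 0.0
    return float(regionprops(m.astype(np.uint8))[0].eccentricity)


def haralick_compactness(mask) -> float:
    """Circularity as mean/std of boundary-to-centroid distances.

    Larger means rounder. Digital figures with perfectly constant radius
    would divide by zero; those return the cap value ``HARALICK_CAP``.
    """
    m = _mask_array(mask)
    b = boundary_pixels(m)
    centroid = np.argwhere(m).mean(axis=0)
    d = np.hypot(*(b - centroid).T)
    mu = d.mean()
    sigma = d.std()
    if sigma == 0:
        return HARALICK_CAP
    return float(mu / sigma)


def discrete_compactness(mask) -> float:
    """Bribiesca's normalized discrete compactness C_DN in [0, 1].

    C_D = (4n - P)/2 with P the count of exposed unit cell sides;
    normalized between C_Dmin = n - 1 (a 1-px-wide chain) and
    C_Dmax = (4n - 4*sqrt(n))/2 (the square). 1 px -> 0 by convention.
    """
    m = _mask_array(mask)
    n = int(m.sum())
    if n == 1:
        return 0.0
    padded = np.pad(m, 1)
    # exposed sides = 4n - 2 * (# interior 4-adjacent pairs)
    horiz = int(np.logical_and(padded[:, 1:], padded[:, :-1]).sum())
    vert = int(np.logical_and(padded[1:, :], padded[:-1, :]).sum())
    perimeter = 4 * n - 2 * (horiz + vert)
    cd = (4 * n - perimeter) / 2.0
    cd_min = n - 1.0
    cd_max = (4 * n - 4 * np.sqrt(n)) / 2.0
    if cd_max <= cd_min:
        return 0.0
    return float(np.clip((cd - cd_min) / (cd_max - cd_min), 0.0, 1.0))


def shape_features(mask) -> dict[str, float]:
    """All eight shape descriptors as a named feature dict."""
    return {
        "shape.max_diam": max_diameter(mask),
        "shape.eq_diam": equivalent_diameter(mask),
        "shape.rad_var": radial_variance(mask),
        "shape.rect": rectangularity(mask),
        "shape.elong": elongation(mask),
        "shape.ecc": eccentricity(mask),
        "shape.har_comp": haralick_compactness(mask),
        "shape.cdn": discrete_compactness(mask),
    }
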