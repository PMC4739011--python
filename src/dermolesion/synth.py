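"""Synthetic dermoscopy-like fixtures with analytic ground truth.

Real dermoscopy archives are commercial, so every stage of the pipeline is
exercised on rendered lesions whose shape, color arrangement and texture
are known in closed form: disks, ellipses and Fourier-perturbed blobs on a
homogeneous "healthy skin" background (so the premise that healthy skin
surrounds the mole holds), with optional concentric / displaced /
quadrant-asymmetric color patterns, checker or noise texture, dark hair
overlays and a black camera frame.

The companion table generator emits class-structured feature tables with
Gaussian class-conditional informative features plus independent noise
features, at the 100/70/70/60 class imbalance of a typical atlas sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import line as draw_line
from skimage.morphology import dilation as morph_dilation, disk as disk_se

from .prep import LABEL_COLUMN

CANVAS_DEFAULT = 512
BACKGROUND_RGB = (190, 175, 165)  # pale skin tone
BACKGROUND_NOISE_SIGMA = 3.0

#: default ring colors (outer to inner) for the concentric pattern:
#: light brown -> brown -> red-brown -> dark-brown core. The core stays
#: clearly brighter than hair so the hair-removal premise (hairs darker
#: than their surroundings) holds on the fixture.
CONCENTRIC_COLORS = ((165, 120, 90), (140, 95, 65), (115, 60, 50), (85, 55, 45))
UNIFORM_COLOR = (125, 90, 70)
ALT_COLOR = (95, 110, 150)  # blue-gray patch for asymmetric variants
HAIR_COLOR = (35, 25, 20)


@dataclass
class LesionSpec:
    """Parameters of one rendered lesion."""

    shape: str = "disk"  # disk | ellipse | blob
    size_px: int = 160  # max diameter of the analytic outline
    blob_amplitude: float = 0.15
    color_pattern: str = "concentric"  # uniform | concentric | displaced | quadrant
    colors: tuple = CONCENTRIC_COLORS
    texture: str = "flat"  # flat | checker | noise
    checker_period: int = 8
    texture_sigma: float = 6.0
    n_hairs: int = 0
    hair_width: int = 2
    frame: bool = False
    frame_width: int = 12
    canvas: int = CANVAS_DEFAULT
    sensor_noise_sigma: float = BACKGROUND_NOISE_SIGMA
    ring_gap_px: float = 3.0
    seed: int = 0


@dataclass
class TableSpec:
    """Parameters of one synthetic feature table."""

    n_per_class: dict = field(
        default_factory=lambda: {"BN": 70, "CN": 100, "MM": 60, "SN": 70}
    )
    n_informative: int = 10
    n_noise: int = 10
    separation: float = 3.0
    sigma: float = 1.0
    #: ratio of the largest to smallest per-class noise scale; values > 1
    #: make class covariances unequal (boundaries quadratic, not linear),
    #: mirroring the unequal within-type variability of real lesion types
    sigma_spread: float = 3.0
    seed: int = 0


def _analytic_mask(spec: LesionSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.canvas
    cy = cx = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = yy - cy, xx - cx
    r_max = spec.size_px / 2.0
    if r_max * 2 >= n:
        raise ValueError("lesion larger than canvas")
    if spec.shape == "disk":
        return dy**2 + dx**2 <= r_max**2
    if spec.shape == "ellipse":
        a, b = r_max, r_max / 2.0
        return (dx / a) ** 2 + (dy / b) ** 2 <= 1.0
    if spec.shape == "blob":
        theta = np.arctan2(dy, dx)
        r = np.hypot(dy, dx)
        radius = np.full_like(theta, r_max * (1 - spec.blob_amplitude))
        for k in range(2, 6):
            amp = spec.blob_amplitude * r_max / k
            phase = rng.uniform(0, 2 * np.pi)
            radius = radius + amp * np.cos(k * theta + phase)
        return r <= radius
    raise ValueError(f"unknown shape {spec.shape!r}")


def _radial_fraction(spec: LesionSpec) -> np.ndarray:
    n = spec.canvas
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    return np.hypot(yy - c, xx - c) / (spec.size_px / 2.0)


def _paint(spec: LesionSpec, mask: np.ndarray) -> np.ndarray:
    n = spec.canvas
    img = np.empty((n, n, 3), dtype=float)
    img[:] = BACKGROUND_RGB
    if spec.color_pattern == "uniform":
        img[mask] = UNIFORM_COLOR
    elif spec.color_pattern == "concentric":
        # nested rings, each separated from the next by a thin band of the
        # outermost color so the digital convex hull of an inner ring never
        # bleeds into its neighbor (a perfect structure then scores
        # concentricity exactly 1)
        colors = spec.colors
        frac = _radial_fraction(spec)
        gap = spec.ring_gap_px / (spec.size_px / 2.0)
        img[mask] = colors[0]
        k = len(colors)
        for i in range(1, k):
            ring = mask & (frac <= 1.0 - i / k)
            img[ring] = colors[i]
            guard = mask & (frac > 1.0 - i / k) & (frac <= 1.0 - i / k + gap)
            img[guard] = colors[0]
    elif spec.color_pattern == "displaced":
        # two side-by-side colors: no core-in-ring structure
        cols = np.arange(n)[None, :] * np.ones((n, 1))
        img[mask & (cols <= (n - 1) / 2)] = UNIFORM_COLOR
        img[mask & (cols > (n - 1) / 2)] = spec.colors[-1]
    elif spec.color_pattern == "quadrant":
        img[mask] = UNIFORM_COLOR
        rows = np.arange(n)[:, None] * np.ones((1, n))
        cols = np.arange(n)[None, :] * np.ones((n, 1))
        quad = (rows < (n - 1) / 2) & (cols < (n - 1) / 2)
        img[mask & quad] = ALT_COLOR
    else:
        raise ValueError(f"unknown color pattern {spec.color_pattern!r}")
    return img


def _texture(spec: LesionSpec, img: np.ndarray, mask: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    if spec.texture == "flat":
        return img
    if spec.texture == "checker":
        n = spec.canvas
        yy, xx = np.mgrid[0:n, 0:n]
        p = spec.checker_period
        pattern = (((yy // p) + (xx // p)) % 2) * 2.0 - 1.0
        img = img.copy()
        img[mask] += (pattern[mask] * spec.texture_sigma)[:, None]
        return img
    if spec.texture == "noise":
        img = img.copy()
        img[mask] += rng.normal(0, spec.texture_sigma, (int(mask.sum()), 3))
        return img
    raise ValueError(f"unknown texture {spec.texture!r}")


def _overlay_hairs(spec: LesionSpec, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = spec.canvas
    hair = np.zeros((n, n), dtype=bool)
    for _ in range(spec.n_hairs):
        side = rng.integers(0, 2)
        if side == 0:  # left-to-right
            r0, r1 = rng.integers(0, n, 2)
            rr, cc = draw_line(int(r0), 0, int(r1), n - 1)
        else:  # top-to-bottom
            c0, c1 = rng.integers(0, n, 2)
            rr, cc = draw_line(0, int(c0), n - 1, int(c1))
        hair[rr, cc] = True
    if spec.hair_width > 1:
        hair = morph_dilation(hair, disk_se(spec.hair_width // 2))
    img = img.copy()
    img[hair] = HAIR_COLOR
    return img


def gen_lesion_image(spec: LesionSpec) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render a lesion; returns (RGB uint8 image, truth mask, truth dict).

    The truth dict holds every descriptor with a closed form on the spec:
    analytic area, diameters, eccentricity, rectangularity, elongation and
    the target concentricity of the color pattern.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _analytic_mask(spec, rng)
    img = _paint(spec, mask)
    img = _texture(spec, img, mask, rng)
    if spec.sensor_noise_sigma > 0:
        img += rng.normal(0, spec.sensor_noise_sigma, img.shape)
    if spec.n_hairs:
        img = _overlay_hairs(spec, img, rng)
    if spec.frame:
        w = spec.frame_width
        img[:w] = 0
        img[-w:] = 0
        img[:, :w] = 0
        img[:, -w:] = 0
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    r = spec.size_px / 2.0
    truth: dict[str, float] = {"area_px": float(mask.sum()), "max_diameter": 2.0 * r}
    if spec.shape == "disk":
        truth.update(
            eccentricity=0.0,
            rectangularity=np.pi / 4.0,
            elongation=1.0,
            radial_variance=0.0,
            analytic_area=np.pi * r**2,
        )
    elif spec.shape == "ellipse":
        truth.update(
            eccentricity=np.sqrt(1 - 0.25),  # b = a/2
            rectangularity=np.pi / 4.0,
            elongation=2.0,
            analytic_area=np.pi * r * (r / 2.0),
        )
    if spec.color_pattern == "concentric":
        truth["concentricity"] = 1.0
    elif spec.color_pattern == "displaced":
        truth["concentricity_max"] = 0.1
    return img, mask, truth


def gen_feature_table(spec: TableSpec) -> pd.DataFrame:
    """Class-structured Gaussian feature table with named columns.

    Informative columns ``inf_*`` get class-specific means (random
    orthonormal directions scaled by ``separation``); noise columns
    ``noise_*`` are standard normal regardless of class.
    """
    rng = np.random.default_rng(spec.seed)
    classes = sorted(spec.n_per_class)
    # every informative feature carries comparable class signal: class means
    # are a per-feature random permutation of evenly spaced levels whose
    # adjacent gap is separation/2 within-class sigmas
    base_levels = (np.arange(len(classes)) - (len(classes) - 1) / 2.0) * spec.separation / 2.0
    means = np.stack(
        [base_levels[rng.permutation(len(classes))] for _ in range(spec.n_informative)],
        axis=1,
    )
    rows, labels = [], []
    for ci, cls in enumerate(classes):
        n_c = spec.n_per_class[cls]
        frac = ci / max(1, len(classes) - 1)
        sigma_c = spec.sigma * spec.sigma_spread ** (frac - 0.5)
        informative = rng.normal(means[ci], sigma_c, size=(n_c, spec.n_informative))
        noise = rng.normal(0.0, 1.0, size=(n_c, spec.n_noise))
        rows.append(np.hstack([informative, noise]))
        labels.extend([cls] * n_c)
    X = np.vstack(rows)
    cols = [f"inf_{i:02d}" for i in range(spec.n_informative)] + [
        f"noise_{i:02d}" for i in range(spec.n_noise)
    ]
    table = pd.DataFrame(X, columns=cols)
    table[LABEL_COLUMN] = labels
    return table
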