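"""Color descriptors of a lesion in CIELAB space.

Lesion colors carry diagnostic weight: a blue nevus is a uniform blue-gray
patch, a Spitz nevus often shows a dark center ringed by brown globules,
and melanomas mix many colors. The descriptors here are: the number of
significantly different colors (from clustering the (a*, b*) chromaticity
of lesion pixels into four clusters), presence of white/black areas,
"concentricity" of the color clusters (how well the smallest color segment
sits inside the next one, as a ring-in-ring structure), the geometric-vs-
brightness centroid distance per channel, and coarse 3-D Lab histogram
distances between regions.

Concentricity is the product of three indices computed on the two color
segments with the smallest convex hulls, S1 (core) and S2 (hull):

* PA — fraction of S1 in its largest 4-connected component (core cohesion);
* CI — fraction of S1 inside the convex hull of S2 (core inclusion);
* HE — fraction of S2 *outside* the convex hull of S1 (hull exclusion).

All three are in [0, 1]; their product is 1 exactly for a cohesive core
surrounded by a clean ring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor
from skimage.measure import label as cc_label
from skimage.morphology import convex_hull_image
from sklearn.cluster import AgglomerativeClustering, KMeans

from .segment import LesionMask

#: minimum (a*, b*) centroid separation for two clusters to count as
#: different colors
COLOR_DISTANCE_TAU = 12.0

#: L* thresholds for white / black pixel classification
WHITE_L_THRESH = 65.0
BLACK_L_THRESH = 15.0

#: a color is "present" if its largest cohesive patch exceeds this lesion
#: area fraction
PRESENCE_AREA_FRAC = 0.01

WARD_SUBSAMPLE_CAP = 10_000
KERNEL_KMEANS_SUBSAMPLE_CAP = 2_000


@dataclass
class ClusterLabeling:
    """Result of clustering lesion-pixel chromaticities into <= 4 groups."""

    labels: np.ndarray  # per-lesion-pixel cluster id, 0-based
    coords: np.ndarray  # (N, 2) row/col of each lesion pixel
    centroids: np.ndarray  # (k, 2) mean (a*, b*) per cluster
    method: str
    shape: tuple[int, int]  # source image shape

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def cluster_mask(self, cluster: int) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        sel = self.coords[self.labels == cluster]
        m[sel[:, 0], sel[:, 1]] = True
        return m


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """sRGB (0-255) -> CIE L*a*b* under D65, as an H x W x 3 float array."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected H x W x 3 RGB image")
    return skcolor.rgb2lab(img.astype(np.uint8))


def _mask_array(mask) -> np.ndarray:
    return mask.pixels if isinstance(mask, LesionMask) else np.asarray(mask, dtype=bool)


def _kernel_kmeans(points: np.ndarray, k: int, sigma: float, rng: np.random.Generator,
                   max_iter: int = 100) -> np.ndarray:
    """Gaussian-kernel k-means on a point set; returns labels.

    Distances in feature space: ||phi(x) - m_c||^2 = K_xx - 2 mean_j K_xj
    + mean_jl K_jl over cluster members.
    """
    n = len(points)
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-d2 / (2.0 * sigma**2))
    # seed from plain k-means for a deterministic, sensible start
    labels = KMeans(n_clusters=k, n_init=5, random_state=int(rng.integers(2**31))).fit_predict(
        points
    )
    for _ in range(max_iter):
        dist = np.full((n, k), np.inf)
        for c in range(k):
            members = labels == c
            m = members.sum()
            if m == 0:
                continue
            within = K[np.ix_(members, members)].sum() / (m * m)
            cross = K[:, members].sum(axis=1) / m
            dist[:, c] = -2.0 * cross + within
        new_labels = dist.argmin(axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return labels


def cluster_ab(
    lab: np.ndarray,
    mask,
    method: str = "kmeans",
    seed: int = 0,
    n_clusters: int = 4,
) -> ClusterLabeling:
    """Cluster the (a*, b*) values of lesion pixels into four color groups.

    ``method``: ``kmeans`` (k-means++ init), ``kernel_kmeans_s1`` /
    ``kernel_kmeans_s2`` (Gaussian kernel, sigma 1 or 2), or ``ward``
    (agglomerative, Euclidean). The kernel and Ward variants run on a
    seeded random subsample when the lesion is large, then assign the
    remaining pixels to the nearest cluster centroid.

    If the lesion holds fewer distinct (a*, b*) values than requested
    clusters, the distinct values become the clusters.
    """
    m = _mask_array(mask)
    coords = np.argwhere(m)
    ab = lab[m][:, 1:3]
    rng = np.random.default_rng(seed)

    distinct = np.unique(ab, axis=0)
    if len(distinct) < n_clusters:
        labels = np.zeros(len(ab), dtype=int)
        for i, v in enumerate(distinct):
            labels[np.all(ab == v, axis=1)] = i
        return ClusterLabeling(labels, coords, distinct.astype(float), method, m.shape)

    if method == "kmeans":
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(ab)
        labels = km.labels_
    elif method in ("kernel_kmeans_s1", "kernel_kmeans_s2"):
        sigma = 1.0 if method.endswith("s1") else 2.0
        cap = KERNEL_KMEANS_SUBSAMPLE_CAP
        if len(ab) > cap:
            idx = rng.choice(len(ab), cap, replace=False)
        else:
            idx = np.arange(len(ab))
        sub_labels = _kernel_kmeans(ab[idx], n_clusters, sigma, rng)
        labels = _assign_nearest(ab, ab[idx], sub_labels, n_clusters)
    elif method == "ward":
        cap = WARD_SUBSAMPLE_CAP
        if len(ab) > cap:
            idx = rng.choice(len(ab), cap, replace=False)
        else:
            idx = np.arange(len(ab))
        sub_labels = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward").fit_predict(
            ab[idx]
        )
        labels = _assign_nearest(ab, ab[idx], sub_labels, n_clusters)
    else:
        raise ValueError(f"unknown clustering method: {method!r}")

    centroids = np.array([ab[labels == c].mean(axis=0) for c in range(n_clusters)
                          if (labels == c).any()])
    # relabel compactly in case a cluster came out empty
    present = [c for c in range(n_clusters) if (labels == c).any()]
    remap = {c: i for i, c in enumerate(present)}
    labels = np.array([remap[c] for c in labels])
    return ClusterLabeling(labels, coords, centroids, method, m.shape)


def _assign_nearest(points, sub_points, sub_labels, k) -> np.ndarray:
    centroids = np.array(
        [sub_points[sub_labels == c].mean(axis=0) for c in range(k) if (sub_labels == c).any()]
    )
    d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def n_colors(clusters: ClusterLabeling, tau: float = COLOR_DISTANCE_TAU) -> int:
    """Number of significantly different colors: max(1, floor(max D / tau))
    over pairwise centroid distances D in the (a*, b*) plane."""
    c = clusters.centroids
    if len(c) < 2:
        return 1
    d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(axis=2))
    return max(1, int(np.floor(d.max() / tau)))


def color_presence(lab: np.ndarray, mask) -> dict[str, bool]:
    """Presence of white (L* > 65) and black (L* < 15) areas in the lesion.

    A color counts as present only if its largest 4-connected patch covers
    more than 1% of the lesion, so scattered bright/dark pixels don't
    trigger it.
    """
    m = _mask_array(mask)
    area = int(m.sum())
    if area == 0:
        raise ValueError("empty lesion mask")
    L = lab[..., 0]
    out = {}
    for name, sel in (("white", (L > WHITE_L_THRESH) & m), ("black", (L < BLACK_L_THRESH) & m)):
        if not sel.any():
            out[name] = False
            continue
        labels = cc_label(sel, connectivity=1)
        largest = np.bincount(labels.ravel())[1:].max()
        out[name] = bool(largest > PRESENCE_AREA_FRAC * area)
    return out


@dataclass
class ConcentricityParts:
    PA: float
    CI: float
    HE: float

    @property
    def concentricity(self) -> float:
        return self.PA * self.CI * self.HE


def _hull_mask(m: np.ndarray) -> np.ndarray:
    if m.sum() == 0:
        return m
    return convex_hull_image(m)


def concentricity(clusters: ClusterLabeling, mask=None) -> ConcentricityParts:
    """Concentric-structure index from the color clustering.

    Clusters are ordered S1..Sk by ascending convex-hull area; PA, CI, HE
    are computed from S1 (core) and S2 (hull) as described in the module
    docstring. Requires at least two nonempty clusters.
    """
    k = clusters.n_clusters
    if k < 2:
        raise ValueError("concentricity needs at least 2 nonempty clusters")
    masks = [clusters.cluster_mask(c) for c in range(k)]
    hull_areas = [int(_hull_mask(m).sum()) for m in masks]
    order = np.argsort(hull_areas, kind="stable")
    s1 = masks[order[0]]
    s2 = masks[order[1]]
    n_s1 = int(s1.sum())
    n_s2 = int(s2.sum())

    cc = cc_label(s1, connectivity=1)
    cc_max = int(np.bincount(cc.ravel())[1:].max())
    pa = cc_max / n_s1

    hull = _hull_mask(s2)
    ci = int((s1 & hull).sum()) / n_s1

    core = _hull_mask(s1)
    he = 1.0 - int((s2 & core).sum()) / n_s2
    return ConcentricityParts(PA=pa, CI=ci, HE=he)


def centroid_distance(channel: np.ndarray, mask) -> float:
    """Distance between the binary centroid and the brightness centroid of
    a channel restricted to the lesion. 0 for homogeneous pigmentation."""
    m = _mask_array(mask)
    vals = np.asarray(channel, dtype=float)[m]
    if vals.min() < 0:
        vals = vals - vals.min()  # shift channels like a* to non-negative weights
    coords = np.argwhere(m)
    geo = coords.mean(axis=0)
    total = vals.sum()
    if total == 0:
        return 0.0
    bright = (coords * vals[:, None]).sum(axis=0) / total
    return float(np.hypot(*(geo - bright)))


# Lab histogram quantization: 4 L* bins over [0, 100], 8 a*/b* bins over [-128, 128)
_L_EDGES = np.linspace(0.0, 100.0, 5)
_AB_EDGES = np.linspace(-128.0, 128.0, 9)


def lab_histogram(lab: np.ndarray, region_mask) -> np.ndarray:
    """Coarse 4 x 8 x 8 normalized Lab histogram of a region (sums to 1)."""
    m = _mask_array(region_mask)
    if not m.any():
        raise ValueError("empty region for histogram")
    vals = lab[m]
    hist, _ = np.histogramdd(vals, bins=(_L_EDGES, _AB_EDGES, _AB_EDGES))
    # clip L* = 100 etc. into the last bin is handled by histogramdd's
    # closed upper edge on the final bin
    return hist / hist.sum()


def hist_distance(ha: np.ndarray, hb: np.ndarray, norm: str = "L1") -> float:
    """L1 or L2 distance between two identically-binned histograms."""
    if ha.shape != hb.shape:
        raise ValueError("histogram binning mismatch")
    diff = (ha - hb).ravel()
    if norm == "L1":
        return float(np.abs(diff).sum())
    if norm == "L2":
        return float(np.sqrt((diff**2).sum()))
    raise ValueError(f"unknown norm {norm!r}")


def color_features(lab: np.ndarray, mask, seed: int = 0) -> dict[str, float]:
    """Named color feature dict for one lesion."""
    m = _mask_array(mask)
    feats: dict[str, float] = {}
    km = cluster_ab(lab, m, method="kmeans", seed=seed)
    feats["color.n_colors"] = float(n_colors(km))
    presence = color_presence(lab, m)
    feats["color.white"] = float(presence["white"])
    feats["color.black"] = float(presence["black"])
    for method, col in (("kmeans", "color.concentricity_km"),
                        ("kernel_kmeans_s1", "color.concentricity_kkm_s1")):
        cl = km if method == "kmeans" else cluster_ab(lab, m, method=method, seed=seed)
        try:
            feats[col] = concentricity(cl).concentricity
        except ValueError:
            feats[col] = np.nan
    for i, ch in enumerate("Lab"):
        feats[f"color.centroid_dist_{ch}"] = centroid_distance(lab[..., i], m)
    return feats
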