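"""Asymmetry descriptors from subregion decompositions of the lesion.

Malignant lesions arrange their local structures non-uniformly, so
asymmetry is quantified by decomposing the lesion three ways — (1) central
part vs border ring of equal area, (2) halves along the moment-ellipse
major and minor axes, (3) quarters from both axes — and measuring how much
a base feature (color histograms, texture statistics, channel variances)
varies across the parts. Quarter-to-whole feature ratios and a
reflection-overlap shape-asymmetry index complete the set.

The shape-asymmetry index reflects the mask about each principal axis and
reports the mismatch (XOR area over lesion area) — a simple principal-axis
reflection index, 0 for a perfectly symmetric outline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color as skcolor

from . import color as colorf
from . import texture as texf
from .segment import LesionMask

KINDS = ("center_border", "halves_major", "halves_minor", "quarters")


def _mask_array(mask) -> np.ndarray:
    return mask.pixels if isinstance(mask, LesionMask) else np.asarray(mask, dtype=bool)


def principal_axes(mask) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centroid and unit major/minor axis directions from second moments.

    Axis signs are fixed (first nonzero component positive) so the
    decomposition is deterministic.
    """
    m = _mask_array(mask)
    coords = np.argwhere(m).astype(float)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    major = evecs[:, 1]
    minor = evecs[:, 0]

    def canon(v):
        nz = v[np.abs(v) > 1e-12]
        return v if (len(nz) == 0 or nz[0] > 0) else -v

    return centroid, canon(major), canon(minor)


@dataclass
class SubregionSet:
    kind: str
    masks: list[np.ndarray]


def decompose(mask, kind: str) -> SubregionSet:
    """Partition the lesion into subregions of the requested kind.

    ``center_border`` finds, by bisection on the distance transform, the
    erosion depth at which the central part holds half the lesion area;
    half-splits assign on-axis pixels to the lower-index side so the parts
    are exactly disjoint and cover the lesion.
    """
    m = _mask_array(mask)
    if m.sum() < 8:
        raise ValueError("lesion too small to decompose")
    if kind == "center_border":
        dist = ndimage.distance_transform_edt(m)
        target = m.sum() / 2.0
        lo, hi = 0.0, float(dist.max())
        for _ in range(60):
            mid = (lo + hi) / 2.0
            if (dist > mid).sum() > target:
                lo = mid
            else:
                hi = mid
        center = dist > (lo + hi) / 2.0
        if not center.any() or center.sum() == m.sum():
            raise ValueError("degenerate center/border split")
        masks = [center, m & ~center]
    elif kind in ("halves_major", "halves_minor", "quarters"):
        centroid, major, minor = principal_axes(m)
        coords = np.argwhere(m).astype(float) - centroid
        pj_major = coords @ major
        pj_minor = coords @ minor
        idx = np.argwhere(m)

        def build(sel):
            out = np.zeros_like(m)
            out[idx[sel, 0], idx[sel, 1]] = True
            return out

        if kind == "halves_major":  # split *by* the major axis line
            masks = [build(pj_minor <= 0), build(pj_minor > 0)]
        elif kind == "halves_minor":
            masks = [build(pj_major <= 0), build(pj_major > 0)]
        else:
            masks = [
                build((pj_major <= 0) & (pj_minor <= 0)),
                build((pj_major <= 0) & (pj_minor > 0)),
                build((pj_major > 0) & (pj_minor <= 0)),
                build((pj_major > 0) & (pj_minor > 0)),
            ]
    else:
        raise ValueError(f"unknown decomposition kind {kind!r}")
    if any(not sm.any() for sm in masks):
        raise ValueError(f"empty subregion in {kind} decomposition")
    return SubregionSet(kind, masks)


def subregion_variance(feature_fn, subregions: SubregionSet) -> float:
    """Population variance of a per-region feature across the subregions."""
    vals = []
    for sm in subregions.masks:
        v = feature_fn(sm)
        if v is None or not np.isfinite(v):
            return float("nan")
        vals.append(v)
    return float(np.var(vals))


def quarter_ratio(f_quarter: float, f_whole: float) -> float:
    """Quadrant-to-whole feature ratio; NaN when the whole-lesion value is 0."""
    if f_whole == 0:
        return float("nan")
    return f_quarter / f_whole


def stoecker_asymmetry(mask) -> tuple[float, float]:
    """Reflection-mismatch asymmetry about the major and minor axes.

    For each principal axis the mask is reflected about the line through
    the centroid and the index is XOR-area / lesion-area (0 = perfect
    mirror symmetry, up to 2 for disjoint reflection).
    """
    m = _mask_array(mask)
    centroid, major, minor = principal_axes(m)
    coords = np.argwhere(m).astype(float)
    area = len(coords)
    out = []
    for axis in (major, minor):
        centered = coords - centroid
        proj = centered @ axis
        reflected = centroid + 2 * proj[:, None] * axis[None, :] - centered
        rr = np.rint(reflected).astype(int)
        ok = (
            (rr[:, 0] >= 0) & (rr[:, 0] < m.shape[0]) & (rr[:, 1] >= 0) & (rr[:, 1] < m.shape[1])
        )
        refl_mask = np.zeros_like(m)
        refl_mask[rr[ok, 0], rr[ok, 1]] = True
        xor = np.logical_xor(m, refl_mask).sum()
        out.append(float(xor) / area)
    return out[0], out[1]


def _pairs(n: int):
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def asymmetry_features(rgb: np.ndarray, gray: np.ndarray, lab: np.ndarray, mask,
                       levels: int = texf.DEFAULT_GRAY_LEVELS) -> dict[str, float]:
    """Full named asymmetry feature dict for one lesion.

    Emits: Lab-histogram L1/L2 distances between the central and border
    parts, between halves, between each quarter and the whole, and between
    quarter pairs (as variances over each set); variances of the GLCM
    measures over quarters; variance and mean of per-quarter a* and hue
    variances; quarter-to-whole ratios of GLCM dissimilarity; and the two
    principal-axis reflection indices.
    """
    m = _mask_array(mask)
    hsv_h = skcolor.rgb2hsv(np.asarray(rgb, dtype=np.uint8))[..., 0]
    feats: dict[str, float] = {}

    cb = decompose(m, "center_border")
    h_center = colorf.lab_histogram(lab, cb.masks[0])
    h_border = colorf.lab_histogram(lab, cb.masks[1])
    feats["asym.hist_l1.center_border"] = colorf.hist_distance(h_center, h_border, "L1")
    feats["asym.hist_l2.center_border"] = colorf.hist_distance(h_center, h_border, "L2")

    quarters = decompose(m, "quarters")
    h_whole = colorf.lab_histogram(lab, m)
    h_q = [colorf.lab_histogram(lab, qm) for qm in quarters.masks]
    for norm in ("L1", "L2"):
        dq_whole = [colorf.hist_distance(h, h_whole, norm) for h in h_q]
        feats[f"asym.hist_{norm.lower()}.quarter_whole_var"] = float(np.var(dq_whole))
        dq_pairs = [colorf.hist_distance(h_q[i], h_q[j], norm) for i, j in _pairs(4)]
        feats[f"asym.hist_{norm.lower()}.quarter_pairs_var"] = float(np.var(dq_pairs))

    for half_kind in ("halves_major", "halves_minor"):
        halves = decompose(m, half_kind)
        ha = colorf.lab_histogram(lab, halves.masks[0])
        hb = colorf.lab_histogram(lab, halves.masks[1])
        for norm in ("L1", "L2"):
            feats[f"asym.hist_{norm.lower()}.{half_kind}"] = colorf.hist_distance(ha, hb, norm)

    # GLCM measures per quarter -> variance over quarters; quantization is
    # shared (whole-lesion) so quarter values are comparable
    q_img = texf.quantize(gray, m, levels)
    glcm_quarters = []
    for qm in quarters.masks:
        try:
            glcm_quarters.append(texf.glcm_measures(texf.glcm(q_img, qm, levels)))
        except ValueError:
            glcm_quarters.append(None)
    whole_glcm = texf.glcm_measures(texf.glcm(q_img, m, levels))
    for key in ("contrast", "corr", "energy", "homog", "maxp", "dissim"):
        vals = [g[key] for g in glcm_quarters if g is not None]
        feats[f"asym.glcm_{key}.quarters_var"] = float(np.var(vals)) if len(vals) == 4 else np.nan
    # quarter-to-whole ratios for GLCM dissimilarity (Eq.-style R_Qi)
    for i, g in enumerate(glcm_quarters, start=1):
        feats[f"asym.rq{i}.glcm_dissim"] = (
            quarter_ratio(g["dissim"], whole_glcm["dissim"]) if g is not None else np.nan
        )

    # per-quarter channel variances of a* and hue
    for ch_name, ch in (("a", lab[..., 1]), ("h", hsv_h)):
        qvars = [float(np.var(ch[qm])) for qm in quarters.masks]
        feats[f"asym.{ch_name}_var.quarters_var"] = float(np.var(qvars))
        feats[f"asym.{ch_name}_var.quarters_mean"] = float(np.mean(qvars))

    smaj, smin = stoecker_asymmetry(m)
    feats["asym.stoecker.major"] = smaj
    feats["asym.stoecker.minor"] = smin
    return feats
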