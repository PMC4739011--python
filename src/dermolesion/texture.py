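"""Texture statistics from co-occurrence and run-length matrices.

Lesion texture is summarized at second order by a gray-level co-occurrence
matrix (GLCM) over the four unit offsets, symmetrized and normalized, and
at higher order by a gray-level run-length matrix (GLRLM). Because a
dermoscopy camera has no reference orientation, the GLRLMs of the four
orientations {0, 45, 90, 135} degrees are summed into a single
orientation-invariant matrix before the eleven run-length measures are
computed.

Both accumulators operate on the lesion region only: intensity levels are
linearly quantized over the region's own min-max range, and pixel pairs or
runs never cross the mask boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segment import LesionMask

DEFAULT_GRAY_LEVELS = 16

#: unit offsets (dy, dx) for 0, 45, 90, 135 degrees
GLCM_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def _mask_array(mask) -> np.ndarray:
    return mask.pixels if isinstance(mask, LesionMask) else np.asarray(mask, dtype=bool)


def quantize(img: np.ndarray, mask, levels: int = DEFAULT_GRAY_LEVELS) -> np.ndarray:
    """Linearly quantize region intensities into levels 1..G.

    Outside-mask pixels are set to 0. A constant region maps to level 1.
    """
    if levels < 2:
        raise ValueError("need at least 2 gray levels")
    m = _mask_array(mask)
    if not m.any():
        raise ValueError("empty region")
    img = np.asarray(img, dtype=float)
    vals = img[m]
    lo, hi = vals.min(), vals.max()
    out = np.zeros(img.shape, dtype=int)
    if hi == lo:
        out[m] = 1
        return out
    q = np.floor((img[m] - lo) / (hi - lo) * levels).astype(int)
    out[m] = np.clip(q, 0, levels - 1) + 1
    return out


@dataclass
class CooccurrenceMatrix:
    P: np.ndarray  # G x G, normalized
    levels: int
    symmetric: bool = True


def glcm(q: np.ndarray, mask, levels: int | None = None, symmetric: bool = True
         ) -> CooccurrenceMatrix:
    """Co-occurrence matrix of a quantized region over the four unit offsets.

    Pairs with either endpoint outside the mask are discarded; counts are
    symmetrized and normalized to sum 1.
    """
    m = _mask_array(mask)
    if levels is None:
        levels = int(q[m].max())
    counts = np.zeros((levels, levels), dtype=float)
    h, w = q.shape
    for dy, dx in GLCM_OFFSETS:
        src_y = slice(max(0, -dy), min(h, h - dy))
        src_x = slice(max(0, -dx), min(w, w - dx))
        dst_y = slice(max(0, dy), min(h, h + dy))
        dst_x = slice(max(0, dx), min(w, w + dx))
        valid = m[src_y, src_x] & m[dst_y, dst_x]
        a = q[src_y, src_x][valid] - 1
        b = q[dst_y, dst_x][valid] - 1
        np.add.at(counts, (a, b), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs in region")
    return CooccurrenceMatrix(counts / total, levels, symmetric)


def glcm_measures(P: CooccurrenceMatrix | np.ndarray) -> dict[str, float]:
    """Contrast, correlation, energy, homogeneity, maximum probability and
    dissimilarity of a normalized co-occurrence matrix."""
    p = P.P if isinstance(P, CooccurrenceMatrix) else np.asarray(P, dtype=float)
    g = p.shape[0]
    i = np.arange(1, g + 1)[:, None] * np.ones((1, g))
    j = i.T
    mu_x = (i * p).sum()
    mu_y = (j * p).sum()
    sig_x = np.sqrt(((i - mu_x) ** 2 * p).sum())
    sig_y = np.sqrt(((j - mu_y) ** 2 * p).sum())
    if sig_x * sig_y > 0:
        corr = (((i - mu_x) * (j - mu_y) * p).sum()) / (sig_x * sig_y)
    else:
        corr = 0.0
    return {
        "contrast": float(((i - j) ** 2 * p).sum()),
        "corr": float(corr),
        "energy": float((p**2).sum()),
        "homog": float((p / (1.0 + (i - j) ** 2)).sum()),
        "maxp": float(p.max()),
        "dissim": float((np.abs(i - j) * p).sum()),
    }


@dataclass
class RunLengthMatrix:
    """Orientation-summed run-length counts: rows = levels 1..G, columns =
    run lengths 1..R."""

    P: np.ndarray  # G x R counts
    n_pixels: int

    @property
    def n_runs(self) -> float:
        return float(self.P.sum())


def _line_runs(levels_1d: np.ndarray, inside_1d: np.ndarray):
    """Yield (level, length) maximal constant runs of a masked 1-D line."""
    run_level = None
    run_len = 0
    for lv, ok in zip(levels_1d, inside_1d):
        if not ok:
            if run_len:
                yield run_level, run_len
            run_level, run_len = None, 0
        elif lv == run_level:
            run_len += 1
        else:
            if run_len:
                yield run_level, run_len
            run_level, run_len = lv, 1
    if run_len:
        yield run_level, run_len


def glrlm(q: np.ndarray, mask, levels: int | None = None) -> RunLengthMatrix:
    """Sum of the run-length matrices of the four orientations.

    Every region pixel belongs to exactly one run per orientation, so the
    length-weighted count satisfies sum_ij j * P[i, j] = 4 n.
    """
    m = _mask_array(mask)
    if levels is None:
        levels = int(q[m].max())
    h, w = q.shape
    max_run = max(h, w)
    P = np.zeros((levels, max_run), dtype=float)

    def accumulate(lines):
        for lv_line, in_line in lines:
            for lv, ln in _line_runs(lv_line, in_line):
                P[lv - 1, ln - 1] += 1

    accumulate((q[r, :], m[r, :]) for r in range(h))  # 0 deg
    accumulate((q[:, c], m[:, c]) for c in range(w))  # 90 deg
    offsets = range(-(h - 1), w)
    accumulate((np.diagonal(q, k)[::-1], np.diagonal(m, k)[::-1]) for k in offsets)  # 135 deg
    qf, mf = np.fliplr(q), np.fliplr(m)
    accumulate((np.diagonal(qf, k)[::-1], np.diagonal(mf, k)[::-1]) for k in offsets)  # 45 deg
    return RunLengthMatrix(P, int(m.sum()))


def glrlm_measures(M: RunLengthMatrix) -> dict[str, float]:
    """Eleven run-length measures of the orientation-summed matrix.

    Run percentage uses the orientation-summed normalizer 4n (each pixel is
    counted in one run per orientation), so RP is in (0, 1].
    """
    P = M.P
    nr = P.sum()
    if nr < 1:
        raise ValueError("empty run-length matrix")
    g, r = P.shape
    i = np.arange(1, g + 1)[:, None].astype(float)
    j = np.arange(1, r + 1)[None, :].astype(float)
    return {
        "sre": float((P / j**2).sum() / nr),
        "lre": float((P * j**2).sum() / nr),
        "gln": float((P.sum(axis=1) ** 2).sum() / nr),
        "rln": float((P.sum(axis=0) ** 2).sum() / nr),
        "rp": float(nr / (4.0 * M.n_pixels)),
        "lgre": float((P / i**2).sum() / nr),
        "hgre": float((P * i**2).sum() / nr),
        "srlge": float((P / (i**2 * j**2)).sum() / nr),
        "srhge": float((P * i**2 / j**2).sum() / nr),
        "lrlge": float((P * j**2 / i**2).sum() / nr),
        "lrhge": float((P * i**2 * j**2).sum() / nr),
    }


def texture_features(gray: np.ndarray, mask, levels: int = DEFAULT_GRAY_LEVELS
                     ) -> dict[str, float]:
    """Named GLCM + GLRLM feature dict for one region."""
    m = _mask_array(mask)
    q = quantize(gray, m, levels)
    feats = {}
    for k, v in glcm_measures(glcm(q, m, levels)).items():
        feats[f"tex.glcm.{k}"] = v
    for k, v in glrlm_measures(glrlm(q, m, levels)).items():
        feats[f"tex.glrlm.{k}"] = v
    return feats
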