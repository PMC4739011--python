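"""Dermoscopic image preprocessing.

Raw dermoscopy photographs carry artifacts that break downstream
segmentation and texture analysis: a black circular/rectangular frame from
the optical mount, camera noise, and dark body hairs crossing the lesion.
The pipeline here is: black-frame removal -> NTSC grayscale conversion ->
median denoising -> black top-hat hair detection -> hair/structure
discrimination -> neighborhood-median inpainting.

The black top-hat transform ``closing(I, b) - I`` responds to structures
that are darker than their surroundings and thinner than the structuring
element; with a disk element a few pixels wide this isolates hairs while
ignoring the (much larger) lesion body.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.measure import label as cc_label, regionprops

# NTSC 1953 luminance weights (R, G, B)
NTSC_WEIGHTS = (0.2989, 0.5870, 0.1140)

# Reference width for scaling pixel-unit parameters across resolutions
REFERENCE_WIDTH_PX = 768


@dataclass(frozen=True)
class StructuringElement:
    """Disk-shaped grayscale structuring element for morphology."""

    radius: int = 5

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError(f"radius must be >= 1, got {self.radius}")

    def footprint(self) -> np.ndarray:
        return morphology.disk(self.radius)


@dataclass
class HairMask:
    """Boolean hair mask plus per-component geometry used for filtering."""

    pixels: np.ndarray
    components: list = field(default_factory=list)

    @property
    def any_hair(self) -> bool:
        return bool(self.pixels.any())


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"expected H x W x 3 RGB image, got shape {img.shape}")
    return img


def to_grayscale_ntsc(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to luminance using the NTSC 1953 weights.

    Returns an integer image: ``round(0.2989 R + 0.5870 G + 0.1140 B)``.
    """
    img = _check_rgb(img)
    w = np.asarray(NTSC_WEIGHTS)
    lum = img.astype(float) @ w
    return np.rint(lum).astype(np.uint8)


def median_denoise(img: np.ndarray, window: int = 5) -> np.ndarray:
    """Median-filter a grayscale image with a ``window x window`` kernel.

    Borders are handled by edge replication so the output has the same
    shape. ``window`` must be odd and >= 3.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    img = np.asarray(img)
    return ndimage.median_filter(img, size=window, mode="nearest")


def remove_black_frame(
    img: np.ndarray,
    dark_thresh: float = 30,
    row_frac: float = 0.9,
) -> tuple[np.ndarray, tuple[int, int, int, int], bool]:
    """Strip the dark frame that surrounds many dermoscopy photographs.

    Iteratively removes outermost rows/columns in which more than
    ``row_frac`` of the pixels have luminance below ``dark_thresh``.

    Returns ``(cropped, (top, bottom, left, right), degenerate)`` where the
    offsets count removed rows/columns per side. If stripping would consume
    the entire image (e.g. an all-black input) the original image is
    returned with ``degenerate=True``.
    """
    img = _check_rgb(img)
    lum = to_grayscale_ntsc(img).astype(float)
    h, w = lum.shape
    top, bottom, left, right = 0, 0, 0, 0

    def dark_frac(line: np.ndarray) -> float:
        return float(np.mean(line < dark_thresh))

    changed = True
    while changed:
        changed = False
        if h - top - bottom < 1 or w - left - right < 1:
            return img, (0, 0, 0, 0), True
        if dark_frac(lum[top, left : w - right]) > row_frac:
            top += 1
            changed = True
            continue
        if dark_frac(lum[h - 1 - bottom, left : w - right]) > row_frac:
            bottom += 1
            changed = True
            continue
        if dark_frac(lum[top : h - bottom, left]) > row_frac:
            left += 1
            changed = True
            continue
        if dark_frac(lum[top : h - bottom, w - 1 - right]) > row_frac:
            right += 1
            changed = True

    if h - top - bottom < 1 or w - left - right < 1:
        return img, (0, 0, 0, 0), True
    cropped = img[top : h - bottom, left : w - right]
    return cropped, (top, bottom, left, right), False


def black_tophat(img: np.ndarray, se: StructuringElement | None = None) -> np.ndarray:
    """Black top-hat transform: grayscale closing minus the input.

    Non-negative everywhere; highlights objects darker than their
    surroundings and smaller than the structuring element (hairs, when the
    element is a small disk).
    """
    if se is None:
        se = StructuringElement()
    img = np.asarray(img, dtype=float)
    # pad with the global median (≈ background level) so dark structures
    # hugging the border still look thin to the closing; edge reflection
    # would double their width and hide them from the transform
    r = se.radius
    padded = np.pad(img, r, mode="constant", constant_values=float(np.median(img)))
    closed = morphology.closing(padded, se.footprint())[r:-r, r:-r]
    return closed - img


def detect_hairs(
    tophat: np.ndarray,
    bin_thresh: float = 20,
    min_length_px: int = 50,
    min_elongation: float = 4.0,
) -> HairMask:
    """Separate hairs from dots/globules in a black top-hat response.

    The response is binarized at ``bin_thresh``; a connected component is
    kept as hair only if its skeleton is at least ``min_length_px`` long
    and its elongation — skeleton length over mean stroke width, i.e.
    ``skeleton_length**2 / area`` — is at least ``min_elongation``. For a
    straight line this equals the major/minor axis ratio, but unlike the
    moment ellipse it stays large for X-shaped clumps of crossing hairs.
    Round structures (dots, globules — diagnostically relevant, not
    artifacts) fail the elongation test and are rejected.
    """
    tophat = np.asarray(tophat, dtype=float)
    binary = tophat > bin_thresh
    out = np.zeros_like(binary)
    comps = []
    if not binary.any():
        return HairMask(out, comps)
    # bridge short gaps where a hair crosses a region of similar darkness
    # (the top-hat response dips below threshold there), so one hair stays
    # one component
    bridged = morphology.closing(binary, morphology.disk(2))
    labels = cc_label(bridged, connectivity=2)
    for prop in regionprops(labels):
        comp_mask = labels == prop.label
        skel_len = int(morphology.skeletonize(comp_mask).sum())
        elong = skel_len**2 / prop.area
        keep = skel_len >= min_length_px and elong >= min_elongation
        comps.append(
            {"label": prop.label, "skeleton_length": skel_len, "elongation": elong, "kept": keep}
        )
        if keep:
            out |= comp_mask
    return HairMask(out, comps)


def inpaint_hairs(img: np.ndarray, hairs: HairMask, dilation_px: int = 2) -> np.ndarray:
    """Replace hair pixels by nearby non-hair values, channel-wise.

    The hair mask is dilated by ``dilation_px`` to cover anti-aliased hair
    borders, then each masked pixel takes the median of the non-hair pixels
    in a window just large enough to contain its nearest non-hair
    neighbors. Deterministic and idempotent: non-hair pixels are never
    touched.
    """
    img = np.asarray(img)
    mask = np.asarray(hairs.pixels, dtype=bool)
    if mask.shape != img.shape[:2]:
        raise ValueError("hair mask shape does not match image")
    if not mask.any():
        return img.copy()
    if dilation_px > 0:
        mask = morphology.dilation(mask, morphology.disk(dilation_px))
    if mask.all():
        raise ValueError("hair mask covers the entire image; nothing to inpaint from")

    out = img.copy()
    # Distance to nearest non-hair pixel bounds the window needed per pixel.
    dist = ndimage.distance_transform_edt(mask)
    ys, xs = np.nonzero(mask)
    h, w = mask.shape
    channels = 1 if img.ndim == 2 else img.shape[2]
    for y, x in zip(ys, xs):
        r = int(np.ceil(dist[y, x])) + 1
        while True:
            y0, y1 = max(0, y - r), min(h, y + r + 1)
            x0, x1 = max(0, x - r), min(w, x + r + 1)
            sel = ~mask[y0:y1, x0:x1]
            if sel.any():
                break
            r *= 2
        if channels == 1:
            out[y, x] = np.median(img[y0:y1, x0:x1][sel])
        else:
            patch = img[y0:y1, x0:x1]
            out[y, x] = np.median(patch[sel], axis=0)
    return out


def preprocess_image(
    img: np.ndarray,
    median_window: int = 5,
    se_radius: int | None = None,
    hair_bin_thresh: float = 20,
    hair_min_length: int | None = None,
    hair_min_elongation: float = 4.0,
    hair_dilation: int = 2,
    frame_dark_thresh: float = 30,
    frame_row_frac: float = 0.9,
) -> dict:
    """Run the full preprocessing chain on an RGB dermoscopy image.

    Order: frame removal -> grayscale -> median denoise -> black top-hat ->
    hair discrimination -> inpainting. Pixel-unit parameters left as None
    are scaled from their defaults at a 768-px reference width.

    Returns a dict with the cropped+inpainted RGB image (``rgb``), the
    denoised grayscale of the inpainted image (``gray``), the hair mask,
    crop offsets, and a degenerate-frame flag.
    """
    img = _check_rgb(img)
    cropped, offsets, degenerate = remove_black_frame(img, frame_dark_thresh, frame_row_frac)
    width = cropped.shape[1]
    scale = width / REFERENCE_WIDTH_PX
    if se_radius is None:
        # floor of 3: the element must stay wider than a typical hair even
        # on low-resolution images
        se_radius = max(3, round(5 * scale))
    if hair_min_length is None:
        hair_min_length = max(10, round(50 * scale))

    gray = to_grayscale_ntsc(cropped)
    gray_dn = median_denoise(gray, median_window)
    th = black_tophat(gray_dn, StructuringElement(se_radius))
    hairs = detect_hairs(th, hair_bin_thresh, hair_min_length, hair_min_elongation)
    rgb_clean = inpaint_hairs(cropped, hairs, hair_dilation) if hairs.any_hair else cropped.copy()
    gray_clean = median_denoise(to_grayscale_ntsc(rgb_clean), median_window)
    return {
        "rgb": rgb_clean,
        "gray": gray_clean,
        "hair_mask": hairs,
        "crop_offsets": offsets,
        "frame_degenerate": degenerate,
    }
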