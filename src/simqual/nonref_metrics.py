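"""Non-reference (quality) metrics: blur, MR artifact and noise measures.

These score a single image without an undistorted reference.  Most of the
classical constructions assume 8-bit integers; thresholds here are scaled by
``L / 255`` (or the image is internally remapped to [0, 255]) so the metrics
transfer to float-valued MR slices with arbitrary intensity ranges.

Blurriness family
    BE (blur effect, re-blur gradient loss), BR / MB (blur ratio and mean
    blur from per-edge inverse blurriness), VL (variance of the Laplacian),
    BEW (mean blurred edge width), JNB (just-noticeable-blur pooled
    distortion) and CPBD (cumulative probability of blur detection).

MR quality
    MLC (mean correlation of adjacent pixel lines, "average structural
    noise") and MSLC (mean correlation of lines half an image apart,
    "average Nyquist ghosting").

Noisiness
    MTV (mean L2-normed intensity gradient).
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
from scipy import ndimage
from skimage import measure

from .core import validate_image
from .normalize import minmax
from .ref_metrics import LOWER, MetricValue, MissingBackendError

__all__ = [
    "blur_effect",
    "blur_ratio_mean_blur",
    "variance_of_laplacian",
    "blurred_edge_widths",
    "jnb",
    "cpbd",
    "mlc",
    "mslc",
    "mean_total_variation",
    "register_learned_quality",
    "learned_quality",
    "NONREF_METRICS",
]


def _image_range(img: np.ndarray, L: float | None) -> float:
    if L is not None:
        return float(L)
    return float(img.max() - img.min())


# ---------------------------------------------------------------------------
# Blurriness metrics
# ---------------------------------------------------------------------------

def blur_effect(image: np.ndarray) -> float:
    """Blur Effect in [0, 1]: loss of gradient energy under strong re-blur.

    A sharp image changes a lot when blurred again (score near 0); an
    already-smooth image barely changes (score near 1).
    """
    img = validate_image(image)
    if img.max() == img.min():
        raise ValueError("blur effect undefined for a constant image")
    return float(measure.blur_effect(img))


def blur_ratio_mean_blur(image: np.ndarray, L: float | None = None,
                         edge_t8: float = 20.0, blur_threshold: float = 0.25):
    """Blur Ratio and Mean Blur from per-edge-pixel inverse blurriness.

    For each candidate edge pixel the *inverse blurriness* is the ratio of
    the center-versus-neighbor-mean difference to the across-edge variation
    (0.5 at an ideal step, → 0 on a smooth ramp).  Edge candidates are
    pixels whose across-edge variation exceeds ``edge_t8 · L/255`` (the
    classical 8-bit threshold rescaled to the image's data range); a pixel
    counts as *blurred* when its inverse blurriness falls below
    ``blur_threshold``.

    Returns ``{"br": blurred/edges, "mb": mean inverse blurriness of the
    blurred pixels}``.  BR rises with blurring (lower is better); MB is
    higher for sharper images.
    """
    img = validate_image(image)
    Lv = _image_range(img, L)
    if Lv <= 0:
        raise ValueError("constant image")
    edge_thresh = edge_t8 * Lv / 255.0

    ibs = []
    for axis in (0, 1):
        fwd = np.roll(img, -1, axis=axis)
        bwd = np.roll(img, 1, axis=axis)
        sl = [slice(1, -1)] * 2
        variation = np.abs(fwd - bwd)[tuple(sl)]
        center = np.abs(img - 0.5 * (fwd + bwd))[tuple(sl)]
        on_edge = variation > edge_thresh
        if on_edge.any():
            ibs.append(center[on_edge] / variation[on_edge])
    if not ibs:
        raise ValueError("no edge pixels detected")
    ib = np.concatenate(ibs)
    blurred = ib < blur_threshold
    br = float(blurred.mean())
    mb = float(ib[blurred].mean()) if blurred.any() else 0.0
    return {"br": br, "mb": mb}


_LAPLACIAN = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


def variance_of_laplacian(image: np.ndarray) -> float:
    """Variance of the 3×3 Laplacian response (reflect boundary)."""
    img = validate_image(image)
    resp = ndimage.convolve(img, _LAPLACIAN, mode="reflect")
    return float(resp.var())


def _vertical_edge_pixels(img: np.ndarray, L: float, t8: float = 20.0,
                          rel: float = 0.2) -> np.ndarray:
    """Vertical-edge mask: Sobel column gradient above threshold + row-local max.

    The threshold is the larger of the rescaled 8-bit constant
    ``t8 · L/255`` and ``rel``·max|gx|, with non-maximum suppression along
    each row so an edge contributes one pixel per crossing.
    """
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    mag = np.abs(gx)
    # Sobel has gain 4 on a unit step; t8 is in plain 8-bit difference units
    thresh = max(t8 * L / 255.0 * 4.0, rel * float(mag.max()))
    strong = mag > thresh
    left = np.roll(mag, 1, axis=1)
    right = np.roll(mag, -1, axis=1)
    local_max = (mag >= left) & (mag >= right)
    mask = strong & local_max
    mask[:, 0] = mask[:, -1] = False
    return mask


def _edge_widths(img: np.ndarray, edge_mask: np.ndarray, tol: float) -> np.ndarray:
    """Per-edge-pixel width: distance between local extrema along the row.

    From each edge pixel, walk left and right while the intensity keeps
    falling/rising by more than ``tol`` per step in the direction of the
    edge's gradient; the width is the index distance between the two
    extrema (1 for an ideal step edge).  ``tol`` plays the role of the one
    quantization level implicit in the original 8-bit formulation — without
    it the walk would follow the arbitrarily long, strictly monotone tails
    that float-valued smoothing produces.
    """
    widths = []
    h, w = img.shape
    rows, cols = np.nonzero(edge_mask)
    for r, c in zip(rows, cols):
        rising = img[r, min(c + 1, w - 1)] >= img[r, max(c - 1, 0)]
        sign = 1.0 if rising else -1.0
        row = sign * img[r]
        left = c
        while left > 0 and row[left - 1] < row[left] - tol:
            left -= 1
        right = c
        while right < w - 1 and row[right + 1] > row[right] + tol:
            right += 1
        widths.append(max(right - left, 1))
    return np.asarray(widths, dtype=np.float64)


def blurred_edge_widths(image: np.ndarray, L: float | None = None) -> float:
    """Mean blurred edge width in pixels (higher = blurrier).

    Vertical edges are detected with a Sobel threshold scaled by the data
    range; each edge's width is the distance between the local intensity
    extrema along its row.
    """
    img = validate_image(image)
    Lv = _image_range(img, L)
    if Lv <= 0:
        raise ValueError("constant image")
    mask = _vertical_edge_pixels(img, Lv)
    if not mask.any():
        raise ValueError("no edge pixels detected")
    return float(_edge_widths(img, mask, tol=Lv / 255.0).mean())


# -- JNB / CPBD -------------------------------------------------------------

_JNB_BETA = 3.6
_JNB_P = 0.63  # probability of blur detection at the just-noticeable width


def _jnb_edges_and_widths(image: np.ndarray, L: float | None, block: int = 64,
                          edge_block_frac: float = 0.002):
    """Shared JNB/CPBD front end on an internal [0, 255] remapping.

    Returns per-edge (width, w_jnb) pairs pooled over *edge blocks*
    (blocks whose edge-pixel count exceeds ``edge_block_frac`` of the block
    area).  The just-noticeable width is 5 px for low-contrast blocks
    (Michelson-style block contrast <= 50 of 255) and 3 px otherwise, per
    the original 8-bit psychophysics.
    """
    img = validate_image(image)
    Lv = _image_range(img, L)
    if Lv <= 0:
        raise ValueError("constant image")
    img8, _ = minmax(img, (0.0, 255.0))
    img8 = np.round(img8)  # the 8-bit grid the psychophysical constants assume
    # fixed 8-bit threshold (no image-relative term): moderate-contrast
    # edges carry most of the blur-detection signal
    mask = _vertical_edge_pixels(img8, 255.0, rel=0.0)
    widths_map = np.zeros(img8.shape)
    if mask.any():
        widths_map[mask] = _edge_widths(img8, mask, tol=1.0)
    h, w = img8.shape
    ratios = []
    n_blocks = 0
    for r0 in range(0, h - block + 1, block):
        for c0 in range(0, w - block + 1, block):
            sl = (slice(r0, r0 + block), slice(c0, c0 + block))
            edges = mask[sl]
            n_edge = int(edges.sum())
            if n_edge <= edge_block_frac * block * block:
                continue
            n_blocks += 1
            contrast = float(img8[sl].max() - img8[sl].min())
            w_jnb = 5.0 if contrast <= 50.0 else 3.0
            ratios.append(widths_map[sl][edges] / w_jnb)
    if not ratios:
        raise ValueError("no edge blocks detected")
    return ratios, n_blocks


def jnb(image: np.ndarray, L: float | None = None) -> float:
    """Just-noticeable-blur distortion (lower = sharper = better quality).

    Per edge block the width/JNB-width ratios are pooled with a Minkowski
    norm (beta 3.6), then pooled again over blocks and normalized by the
    number of edge blocks.
    """
    ratios, n_blocks = _jnb_edges_and_widths(image, L)
    block_d = [float(np.sum(r**_JNB_BETA) ** (1.0 / _JNB_BETA)) for r in ratios]
    d = float(np.sum(np.asarray(block_d) ** _JNB_BETA) ** (1.0 / _JNB_BETA))
    return d / n_blocks


def cpbd(image: np.ndarray, L: float | None = None) -> float:
    """Cumulative probability of blur detection, in [0, 1] (higher = sharper).

    The probability that a human detects blur at an edge is modeled as
    ``1 − exp(−(w / w_jnb)^3.6)``; CPBD is the fraction of edges whose
    probability stays at or below the just-noticeable level 0.63.
    """
    ratios, _ = _jnb_edges_and_widths(image, L)
    all_ratios = np.concatenate(ratios)
    p_blur = 1.0 - np.exp(-(all_ratios**_JNB_BETA))
    return float((p_blur <= _JNB_P).mean())


# ---------------------------------------------------------------------------
# MR quality metrics
# ---------------------------------------------------------------------------

def _pair_correlations(lines_a: np.ndarray, lines_b: np.ndarray) -> list[float]:
    """Pearson correlation per line pair; zero-variance pairs are skipped.

    Constancy is judged by an exact zero peak-to-peak span: ``std`` of a
    constant line can come out as ~1e-16 through roundoff, which would make
    corrcoef correlate numerical noise.
    """
    out = []
    for a, b in zip(lines_a, lines_b):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        out.append(float(np.corrcoef(a, b)[0, 1]))
    return out


def mlc(image: np.ndarray) -> float:
    """Mean line correlation: mean Pearson r over all adjacent row pairs and
    adjacent column pairs.  High on anatomically smooth images; structural
    noise, stripes and additive noise all decorrelate neighboring lines.
    """
    img = validate_image(image)
    if img.shape[0] < 4 or img.shape[1] < 4:
        raise ValueError("mlc needs at least a 4x4 image")
    corrs = _pair_correlations(img[:-1], img[1:])
    corrs += _pair_correlations(img.T[:-1], img.T[1:])
    if not corrs:
        raise ValueError("all line pairs have zero variance")
    return float(np.mean(corrs))


def mslc(image: np.ndarray) -> float:
    """Mean shifted line correlation: line pairs half an image apart.

    Rows ``(i, i + H/2)`` and columns ``(j, j + W/2)``; odd dimensions are
    center-cropped by one pixel so the half-image shift is integer.
    Nyquist ghosts and phase-coherent stripe artifacts raise this score.
    """
    img = validate_image(image)
    h, w = img.shape
    img = img[: h - h % 2, : w - w % 2]
    h, w = img.shape
    if h < 4 or w < 4:
        raise ValueError("mslc needs at least a 4x4 image")
    corrs = _pair_correlations(img[: h // 2], img[h // 2 :])
    corrs += _pair_correlations(img.T[: w // 2], img.T[w // 2 :])
    if not corrs:
        raise ValueError("all line pairs have zero variance")
    return float(np.mean(corrs))


# ---------------------------------------------------------------------------
# Noise metric
# ---------------------------------------------------------------------------

def mean_total_variation(image: np.ndarray) -> float:
    """Mean L2-normed intensity gradient (noisiness; 0 for constant images).

    Gradients are central differences with one-sided differences at the
    borders, so a unit ramp scores exactly 1.
    """
    img = validate_image(image)
    dy, dx = np.gradient(img)
    return float(np.hypot(dx, dy).mean())


# ---------------------------------------------------------------------------
# Learned-quality adapters (BRISQUE / NIQE): contract only
# ---------------------------------------------------------------------------

_QUALITY_BACKENDS: dict[str, Callable] = {}
_QUALITY_NAMES = ("brisque", "niqe")


def register_learned_quality(name: str, fn: Callable) -> None:
    """Register ``fn(image_8bit) -> float`` as a learned-quality backend."""
    if name not in _QUALITY_NAMES:
        raise ValueError(f"unknown learned quality metric {name!r}")
    _QUALITY_BACKENDS[name] = fn


def learned_quality(name: str, image: np.ndarray) -> MetricValue:
    """Delegate to a registered BRISQUE/NIQE backend on an 8-bit binned input."""
    from .normalize import binning

    if name not in _QUALITY_NAMES:
        raise ValueError(f"unknown learned quality metric {name!r}")
    if name not in _QUALITY_BACKENDS:
        raise MissingBackendError(
            f"no backend registered for {name!r}: install the optional "
            f"package and call register_learned_quality({name!r}, fn)"
        )
    img8, _ = binning(validate_image(image), 256)
    value = float(_QUALITY_BACKENDS[name](img8))
    return MetricValue(name, value, LOWER)


#: Name → callable(I, L) for the harness.
NONREF_METRICS: dict[str, Callable] = {
    "be": lambda I, L=None: blur_effect(I),
    "br": lambda I, L=None: blur_ratio_mean_blur(I, L)["br"],
    "mb": lambda I, L=None: blur_ratio_mean_blur(I, L)["mb"],
    "vl": lambda I, L=None: variance_of_laplacian(I),
    "bew": lambda I, L=None: blurred_edge_widths(I, L),
    "jnb": lambda I, L=None: jnb(I, L),
    "cpbd": lambda I, L=None: cpbd(I, L),
    "mlc": lambda I, L=None: mlc(I),
    "mslc": lambda I, L=None: mslc(I),
    "mtv": lambda I, L=None: mean_total_variation(I),
    "brisque": lambda I, L=None: float(learned_quality("brisque", I)),
    "niqe": lambda I, L=None: float(learned_quality("niqe", I)),
}
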