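"""Intensity normalization methods for MR images.

MR intensities are non-quantitative: the same tissue maps to different values
depending on scanner and protocol, so images are brought to a common scale
before similarity or quality assessment.  Six methods are provided:

* ``minmax`` — affine map onto a target range ``[j1, j2]``
* ``cminmax`` — percentile clipping followed by minmax (robust to outliers)
* ``zscore`` — zero mean, unit (population) standard deviation
* ``quantile`` — zero median, unit inter-quartile range
* ``binning`` — quantization to ``B`` (default 256) equidistant integer bins
* ``pl`` — two-piece linear histogram standardization matching three
  landmarks (low percentile, foreground histogram mode, high percentile)
  fitted on a reference dataset

Each ``apply`` returns the normalized image together with a
:class:`NormalizationRecord` holding the fitted parameters; for the affine
methods the record supports exact inversion, mirroring the workflow where a
synthesized image is mapped back to the original intensity range before
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import validate_image

__all__ = [
    "NormalizationRecord",
    "minmax",
    "cminmax",
    "zscore",
    "quantile_norm",
    "binning",
    "pl_fit",
    "pl_apply",
    "normalize",
    "invert",
    "NORMALIZATIONS",
]


@dataclass
class NormalizationRecord:
    """Fitted parameters of one normalization applied to one image.

    Affine methods store ``scale`` (a > 0) and ``shift`` (b) such that
    ``output = a * input + b``; that map is exactly invertible.  Method
    specific extras (clip values, bin edges, landmarks) live in ``params``.
    """

    method: str
    scale: float | None = None
    shift: float | None = None
    params: dict = field(default_factory=dict)

    @property
    def invertible(self) -> bool:
        return self.scale is not None


def _affine_to_target(lo: float, hi: float, target: Sequence[float]) -> tuple[float, float]:
    j1, j2 = float(target[0]), float(target[1])
    if hi <= lo:
        raise ValueError("zero data range: constant input cannot be normalized")
    a = (j2 - j1) / (hi - lo)
    b = j1 - a * lo
    if a <= 0:
        raise ValueError("target range must satisfy j1 < j2")
    return a, b


def minmax(image: np.ndarray, target: Sequence[float] = (0.0, 1.0)):
    """Affine map of the intensity range onto ``[j1, j2]`` exactly."""
    img = validate_image(image)
    lo, hi = float(img.min()), float(img.max())
    a, b = _affine_to_target(lo, hi, target)
    out = (img - lo) * a + float(target[0])
    # pin the extremes exactly despite float rounding
    out[img == lo] = float(target[0])
    out[img == hi] = float(target[1])
    rec = NormalizationRecord("minmax", scale=a, shift=b, params={"target": tuple(target)})
    return out, rec


def cminmax(image: np.ndarray, p: float = 0.05, target: Sequence[float] = (0.0, 1.0)):
    """Clip at the ``p``/``1−p`` percentiles, then minmax to ``[j1, j2]``.

    The default ``p = 0.05`` clips the lowest and highest 5% of intensities,
    making the map robust to extreme outliers.
    """
    img = validate_image(image)
    if not 0.0 < p < 0.5:
        raise ValueError("clip fraction p must lie in (0, 0.5)")
    lo, hi = np.percentile(img, [100.0 * p, 100.0 * (1.0 - p)])
    if hi <= lo:
        raise ValueError("degenerate clip percentiles (image nearly constant)")
    clipped = np.clip(img, lo, hi)
    a, b = _affine_to_target(float(lo), float(hi), target)
    out = (clipped - lo) * a + float(target[0])
    out[clipped == lo] = float(target[0])
    out[clipped == hi] = float(target[1])
    rec = NormalizationRecord(
        "cminmax",
        scale=a,
        shift=b,
        params={"target": tuple(target), "p": p, "clip_low": float(lo), "clip_high": float(hi)},
    )
    return out, rec


def zscore(image: np.ndarray):
    """Shift to mean 0 and scale to unit population standard deviation."""
    img = validate_image(image)
    mu = float(img.mean())
    sigma = float(img.std())  # population std: deterministic, no n−1 ambiguity
    if sigma <= 0:
        raise ValueError("zero standard deviation: constant input")
    a = 1.0 / sigma
    b = -mu / sigma
    rec = NormalizationRecord("zscore", scale=a, shift=b, params={"mean": mu, "std": sigma})
    return a * img + b, rec


def quantile_norm(image: np.ndarray):
    """Shift to median 0 and scale to unit inter-quartile range.

    Percentiles use linear interpolation between order statistics.
    """
    img = validate_image(image)
    p25, med, p75 = np.percentile(img, [25.0, 50.0, 75.0])
    iqr = float(p75 - p25)
    if iqr <= 0:
        raise ValueError("zero inter-quartile range")
    a = 1.0 / iqr
    b = -float(med) / iqr
    rec = NormalizationRecord(
        "quantile", scale=a, shift=b, params={"median": float(med), "iqr": iqr}
    )
    return a * img + b, rec


def binning(image: np.ndarray, B: int = 256):
    """Map intensities to ``B`` equidistant integer bins over [min, max].

    Bin index = ``floor((x − min) / (max − min) · B)`` with the global
    maximum assigned to bin ``B − 1`` (half-open equidistant bins with exact
    boundary behavior).  The output is integer-valued in ``[0, B−1]``;
    quantization loses information, so no inverse is defined.
    """
    img = validate_image(image)
    if B < 2:
        raise ValueError("number of bins B must be >= 2")
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        raise ValueError("constant image cannot be binned")
    idx = np.floor((img - lo) / (hi - lo) * B)
    out = np.clip(idx, 0, B - 1)
    rec = NormalizationRecord(
        "binning", params={"B": B, "min": lo, "max": hi}
    )
    return out, rec


# ---------------------------------------------------------------------------
# Piece-wise linear histogram standardization
# ---------------------------------------------------------------------------

def _image_landmarks(img: np.ndarray, p_low: float, p_high: float, bins: int = 256):
    """(low percentile, foreground-mode, high percentile) of one image.

    The histogram mode is estimated on nonzero pixels only: skull-stripped
    slices have an exactly-zero background that would otherwise dominate.
    """
    p1, p2 = np.percentile(img, [p_low * 100.0, p_high * 100.0])
    fg = img[img != 0]
    if fg.size == 0:
        raise ValueError("image has no nonzero pixels for mode estimation")
    hist, edges = np.histogram(fg, bins=bins)
    k = int(np.argmax(hist))
    mode = 0.5 * (edges[k] + edges[k + 1])
    if not (p1 < mode < p2):
        raise ValueError(
            f"histogram mode {mode:.4g} does not lie strictly between the "
            f"percentile landmarks ({p1:.4g}, {p2:.4g})"
        )
    return float(p1), float(mode), float(p2)


def pl_fit(images: Sequence[np.ndarray], p_low: float = 0.01, p_high: float = 0.99):
    """Fit standard landmarks ``(s1, m_s, s2)`` from training images.

    Landmarks of each image (``p_low`` percentile, foreground histogram mode,
    ``p_high`` percentile) are averaged.  With a single image the standard
    landmarks are that image's own landmarks.
    """
    if len(images) < 1:
        raise ValueError("pl_fit requires at least one training image")
    marks = np.array(
        [_image_landmarks(validate_image(im), p_low, p_high) for im in images]
    )
    s1, m_s, s2 = marks.mean(axis=0)
    return float(s1), float(m_s), float(s2)


def pl_apply(
    image: np.ndarray,
    landmarks: Sequence[float],
    p_low: float = 0.01,
    p_high: float = 0.99,
):
    """Two-piece linear map of the image histogram onto standard landmarks.

    ``[p1, mode]`` of the image is mapped linearly onto ``[s1, m_s]`` and
    ``[mode, p2]`` onto ``[m_s, s2]``; the two affine pieces are continuous
    and monotone, and extend linearly beyond the percentile landmarks.
    """
    img = validate_image(image)
    s1, m_s, s2 = (float(v) for v in landmarks)
    p1, mode, p2 = _image_landmarks(img, p_low, p_high)
    a_lo = (m_s - s1) / (mode - p1)
    a_hi = (s2 - m_s) / (p2 - mode)
    out = np.where(
        img <= mode,
        s1 + a_lo * (img - p1),
        m_s + a_hi * (img - mode),
    )
    rec = NormalizationRecord(
        "pl",
        params={
            "standard": (s1, m_s, s2),
            "image_landmarks": (p1, mode, p2),
            "slopes": (a_lo, a_hi),
        },
    )
    return out, rec


def invert(image: np.ndarray, record: NormalizationRecord) -> np.ndarray:
    """Undo an affine normalization: recovers the original intensities.

    Defined for minmax, cminmax (exact on unclipped pixels), zscore and
    quantile; binning and pl are not affinely invertible.
    """
    if not record.invertible:
        raise ValueError(f"normalization {record.method!r} is not invertible")
    return (np.asarray(image, dtype=np.float64) - record.shift) / record.scale


def _none(image: np.ndarray):
    return validate_image(image), NormalizationRecord("none", scale=1.0, shift=0.0)


NORMALIZATIONS = {
    "none": _none,
    "minmax": minmax,
    "cminmax": cminmax,
    "zscore": zscore,
    "quantile": quantile_norm,
    "binning": binning,
}


def normalize(image: np.ndarray, method: str, **kwargs):
    """Apply a normalization selected by name.

    ``pl`` requires fitted landmarks and is applied via :func:`pl_apply`.
    """
    if method == "pl":
        return pl_apply(image, **kwargs)
    try:
        fn = NORMALIZATIONS[method]
    except KeyError:
        raise ValueError(
            f"unknown normalization {method!r}; choose from "
            f"{sorted(NORMALIZATIONS) + ['pl']}"
        ) from None
    return fn(image, **kwargs)
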