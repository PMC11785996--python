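"""Reference (similarity) metrics with explicit data-range semantics.

All metrics compare a test image ``I`` against a spatially aligned reference
``R`` of equal shape.  Metrics with internal stabilizing constants (SSIM
family, PSNR) take a data-range parameter ``L``; the default is the joint
pair range ``L_{I,R}``, because a single-image range would make the score
depend on which image is called the reference.

Stabilizing constants follow the original SSIM definition
``C1 = (k1·L)^2``, ``C2 = (k2·L)^2``, ``C3 = C2/2`` with ``k1 = 0.01``,
``k2 = 0.03``.  Note that a very large ``L`` makes the constants dominate
and drives SSIM towards 1 regardless of content — the reason the choice of
``L`` must be reported alongside any SSIM value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

from .core import DataRange, require_positive_range, validate_image
from .normalize import binning, minmax

__all__ = [
    "MetricValue",
    "ssim",
    "ms_ssim",
    "cw_ssim",
    "psnr",
    "mse",
    "error_metrics",
    "nmi",
    "pcc",
    "register_learned_metric",
    "learned_metric",
    "MissingBackendError",
    "REFERENCE_METRICS",
]

HIGHER = "higher_is_similar"
LOWER = "lower_is_similar"


@dataclass(frozen=True)
class MetricValue:
    """One metric score plus its direction and the data range it used."""

    name: str
    value: float
    direction: str
    data_range: DataRange | None = None

    def __float__(self) -> float:
        return float(self.value)


def _check_pair(image: np.ndarray, reference: np.ndarray):
    I = validate_image(image)
    R = validate_image(reference)
    if I.shape != R.shape:
        raise ValueError(f"shape mismatch: {I.shape} vs {R.shape}")
    return I, R


def _resolve_L(I: np.ndarray, R: np.ndarray, L) -> tuple[float, DataRange]:
    if L is None:
        dr = DataRange(float(max(I.max(), R.max()) - min(I.min(), R.min())), "pair")
    elif isinstance(L, DataRange):
        dr = L
    else:
        dr = DataRange(float(L), "pair")
    return require_positive_range(dr), dr


# ---------------------------------------------------------------------------
# SSIM family
# ---------------------------------------------------------------------------

def ssim(
    image: np.ndarray,
    reference: np.ndarray,
    L: float | DataRange | None = None,
    k1: float = 0.01,
    k2: float = 0.03,
) -> MetricValue:
    """Structural similarity: local luminance, contrast and structure.

    Uses the original formulation's 11×11 Gaussian window (sigma 1.5) and
    population (not sample) covariances; the score is the mean of the local
    SSIM map.  Symmetric in (I, R) for a shared ``L``; ssim(I, I) = 1.
    """
    I, R = _check_pair(image, reference)
    Lv, dr = _resolve_L(I, R, L)
    value = structural_similarity(
        I,
        R,
        win_size=11,
        data_range=Lv,
        gaussian_weights=True,
        sigma=1.5,
        use_sample_covariance=False,
        K1=k1,
        K2=k2,
    )
    return MetricValue("ssim", float(value), HIGHER, dr)


def _gaussian_window(sigma: float = 1.5, size: int = 11) -> np.ndarray:
    x = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(x**2) / (2 * sigma**2))
    return g / g.sum()


def _ssim_components(I, R, L, k1=0.01, k2=0.03):
    """Mean luminance·structure (full SSIM) and contrast-structure terms.

    Computed with the 11-tap Gaussian window; the border where the window
    leaves the image is cropped before averaging.
    """
    C1 = (k1 * L) ** 2
    C2 = (k2 * L) ** 2
    win = _gaussian_window()

    def filt(x):
        out = ndimage.convolve1d(x, win, axis=0, mode="reflect")
        return ndimage.convolve1d(out, win, axis=1, mode="reflect")

    mu_i, mu_r = filt(I), filt(R)
    var_i = filt(I * I) - mu_i**2
    var_r = filt(R * R) - mu_r**2
    cov = filt(I * R) - mu_i * mu_r
    lum = (2 * mu_i * mu_r + C1) / (mu_i**2 + mu_r**2 + C1)
    cs = (2 * cov + C2) / (var_i + var_r + C2)
    pad = len(win) // 2
    sl = (slice(pad, -pad), slice(pad, -pad))
    return float((lum * cs)[sl].mean()), float(cs[sl].mean())


_MS_SSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


def ms_ssim(
    image: np.ndarray,
    reference: np.ndarray,
    L: float | DataRange | None = None,
) -> MetricValue:
    """Multi-scale SSIM over the original and four dyadically downscaled images.

    The contrast-structure term is taken at all five scales and the
    luminance term at the coarsest only, combined with the standard
    published exponents.  Requires min(H, W) >= 176 so an 11-tap window is
    valid at the fifth scale.  Negative contrast-structure responses are
    clamped at zero before exponentiation.
    """
    I, R = _check_pair(image, reference)
    if min(I.shape) < 176:
        raise ValueError(
            "ms_ssim needs min(H, W) >= 176 so that five dyadic scales "
            "support an 11x11 window"
        )
    Lv, dr = _resolve_L(I, R, L)
    terms = []
    for scale in range(5):
        full, cs = _ssim_components(I, R, Lv)
        terms.append(full if scale == 4 else cs)
        if scale < 4:
            I = _downsample(I)
            R = _downsample(R)
    value = 1.0
    for w, t in zip(_MS_SSIM_WEIGHTS, terms):
        value *= max(t, 0.0) ** w
    return MetricValue("ms_ssim", float(value), HIGHER, dr)


def _downsample(x: np.ndarray) -> np.ndarray:
    """2×2 average pooling (odd trailing row/col dropped)."""
    h, w = x.shape
    x = x[: h - h % 2, : w - w % 2]
    return 0.25 * (x[::2, ::2] + x[1::2, ::2] + x[::2, 1::2] + x[1::2, 1::2])


# ---------------------------------------------------------------------------
# Complex-wavelet SSIM
# ---------------------------------------------------------------------------

def _log_gabor_bank(shape, levels: int, orientations: int):
    """Complex log-Gabor filter bank in the frequency domain.

    Radial log-Gabor profiles at ``levels`` dyadic scales crossed with
    ``orientations`` angular Gaussians on a half-plane; the spatial-domain
    responses are therefore complex (analytic), which is what lets CW-SSIM
    tolerate small phase shifts, i.e. small spatial translations.  The bank
    starts one octave below Nyquist: the finest octave is dominated by
    pixel noise rather than structure and is excluded, as in steerable-
    pyramid CW-SSIM implementations that drop the high-pass residual.
    """
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    radius = np.hypot(fx, fy)
    radius[0, 0] = 1.0  # avoid log(0); DC is zeroed below
    theta = np.arctan2(fy, fx)
    sigma_r = 0.65
    sigma_theta = np.pi / orientations
    bank = []
    for lev in range(levels):
        f0 = 0.165 / (2**lev)
        radial = np.exp(-(np.log(radius / f0) ** 2) / (2 * np.log(sigma_r) ** 2))
        radial[0, 0] = 0.0
        for k in range(orientations):
            angle = k * np.pi / orientations
            d = np.angle(np.exp(1j * (theta - angle)))
            angular = np.exp(-(d**2) / (2 * sigma_theta**2))
            bank.append(radial * angular)
    return bank


def cw_ssim(
    image: np.ndarray,
    reference: np.ndarray,
    levels: int = 4,
    orientations: int = 8,
    K: float | None = None,
    window: int = 7,
    L: float | DataRange | None = None,
) -> MetricValue:
    """Complex-wavelet SSIM: similarity of complex subband coefficients.

    Per subband, the index ``(2·|Σ c_I conj(c_R)| + K) / (Σ|c_I|² +
    Σ|c_R|² + K)`` is evaluated over sliding windows and averaged; subband
    means are averaged over the bank.  Coefficient magnitudes are invariant
    to small translations, so the index degrades only gradually for shifts
    of a few pixels while still penalizing large displacements.  ``K`` is a
    small stabilizer scaled with the squared data range.
    """
    I, R = _check_pair(image, reference)
    Lv, dr = _resolve_L(I, R, L)
    if K is None:
        K = 1e-4 * Lv**2
    fI = np.fft.fft2(I)
    fR = np.fft.fft2(R)
    scores = []
    for filt in _log_gabor_bank(I.shape, levels, orientations):
        cI = np.fft.ifft2(fI * filt)
        cR = np.fft.ifft2(fR * filt)
        prod = cI * np.conj(cR)
        num_re = ndimage.uniform_filter(prod.real, window)
        num_im = ndimage.uniform_filter(prod.imag, window)
        den = ndimage.uniform_filter(np.abs(cI) ** 2 + np.abs(cR) ** 2, window)
        n = window * window
        idx = (2 * np.hypot(num_re, num_im) * n + K) / (den * n + K)
        scores.append(float(idx.mean()))
    return MetricValue("cw_ssim", float(np.mean(scores)), HIGHER, dr)


# ---------------------------------------------------------------------------
# PSNR and error metrics
# ---------------------------------------------------------------------------

def mse(image: np.ndarray, reference: np.ndarray) -> float:
    I, R = _check_pair(image, reference)
    return float(np.mean((I - R) ** 2))


def psnr(
    image: np.ndarray,
    reference: np.ndarray,
    L: float | DataRange | None = None,
) -> MetricValue:
    """Peak signal-to-noise ratio: ``10·log10(L² / MSE)`` in dB.

    ``+inf`` for identical images; strictly decreasing in MSE.
    """
    I, R = _check_pair(image, reference)
    Lv, dr = _resolve_L(I, R, L)
    err = mse(I, R)
    if err == 0:
        return MetricValue("psnr", math.inf, HIGHER, dr)
    return MetricValue("psnr", 10.0 * math.log10(Lv**2 / err), HIGHER, dr)


def error_metrics(image: np.ndarray, reference: np.ndarray) -> dict[str, float]:
    """MSE, RMSE, MAE and NMSE (MSE normalized by the reference variance).

    NMSE divides by ``sigma_R^2``: the same pixel errors count as more
    dissimilar against a homogeneous reference than against one with large
    intensity variation.  NMSE is intentionally asymmetric in (I, R).
    """
    I, R = _check_pair(image, reference)
    err = float(np.mean((I - R) ** 2))
    out = {
        "mse": err,
        "rmse": math.sqrt(err),
        "mae": float(np.mean(np.abs(I - R))),
    }
    var_r = float(R.var())
    if var_r <= 0:
        raise ValueError("NMSE undefined: reference image is constant")
    out["nmse"] = err / var_r
    return out


# ---------------------------------------------------------------------------
# Statistical dependency metrics
# ---------------------------------------------------------------------------

def nmi(image: np.ndarray, reference: np.ndarray, B: int = 256) -> MetricValue:
    """Normalized mutual information ``(H(I) + H(R)) / H(I, R)`` in [1, 2].

    Each image is first quantized to ``B`` equidistant bins over its own
    min–max (so the score is invariant to positive affine rescaling of
    either image); entropies are Shannon entropies of the joint 2-D
    histogram.  Identical non-constant images attain the upper end 2.
    """
    I, R = _check_pair(image, reference)
    bi, _ = binning(I, B)
    br, _ = binning(R, B)
    joint = np.zeros((B, B), dtype=np.int64)
    np.add.at(joint, (bi.astype(np.intp).ravel(), br.astype(np.intp).ravel()), 1)
    pj = joint / joint.sum()
    pi = pj.sum(axis=1)
    pr = pj.sum(axis=0)

    def entropy(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    h_joint = entropy(pj.ravel())
    if h_joint <= 0:
        raise ValueError("NMI undefined for constant images (zero entropy)")
    value = (entropy(pi) + entropy(pr)) / h_joint
    return MetricValue("nmi", value, HIGHER)


def pcc(image: np.ndarray, reference: np.ndarray) -> MetricValue:
    """Pearson correlation of intensities over all pixel locations, in [−1, 1]."""
    I, R = _check_pair(image, reference)
    if I.std() == 0 or R.std() == 0:
        raise ValueError("PCC undefined for a constant image")
    value = float(np.corrcoef(I.ravel(), R.ravel())[0, 1])
    return MetricValue("pcc", value, HIGHER)


# ---------------------------------------------------------------------------
# Learned-metric adapters (LPIPS / DISTS): contract only, no weights shipped
# ---------------------------------------------------------------------------

class MissingBackendError(RuntimeError):
    """Raised when a learned metric is requested without a registered backend."""


_LEARNED_BACKENDS: dict[str, Callable] = {}

#: Input range each learned backend expects (enforced via minmax here).
_LEARNED_RANGES = {"lpips": (-1.0, 1.0), "dists": (0.0, 1.0)}


def register_learned_metric(name: str, fn: Callable) -> None:
    """Register a callable ``fn(I, R) -> float`` as a learned-metric backend."""
    if name not in _LEARNED_RANGES:
        raise ValueError(f"unknown learned metric {name!r}; expected one of "
                         f"{sorted(_LEARNED_RANGES)}")
    _LEARNED_BACKENDS[name] = fn


def learned_metric(name: str, image: np.ndarray, reference: np.ndarray) -> MetricValue:
    """Delegate to a registered LPIPS/DISTS backend.

    Both inputs are minmax-normalized to the backend's expected range
    ([−1, 1] for lpips, [0, 1] for dists) before delegation.  The value of
    these metrics is their pretrained weights, which this package does not
    ship; without a registered backend a structured error is raised rather
    than silently skipping the metric.
    """
    if name not in _LEARNED_RANGES:
        raise ValueError(f"unknown learned metric {name!r}")
    if name not in _LEARNED_BACKENDS:
        raise MissingBackendError(
            f"no backend registered for {name!r}: install the optional "
            f"'{name}' package and call register_learned_metric({name!r}, fn)"
        )
    target = _LEARNED_RANGES[name]
    I, _ = minmax(image, target)
    R, _ = minmax(reference, target)
    value = float(_LEARNED_BACKENDS[name](I, R))
    return MetricValue(name, value, LOWER)


#: Name → callable(I, R, L) for the harness.  Learned metrics are looked up
#: through the adapter so a missing backend fails loudly, not silently.
REFERENCE_METRICS: dict[str, Callable] = {
    "ssim": lambda I, R, L=None: float(ssim(I, R, L)),
    "ms_ssim": lambda I, R, L=None: float(ms_ssim(I, R, L)),
    "cw_ssim": lambda I, R, L=None: float(cw_ssim(I, R, L=L)),
    "psnr": lambda I, R, L=None: float(psnr(I, R, L)),
    "mse": lambda I, R, L=None: error_metrics(I, R)["mse"],
    "rmse": lambda I, R, L=None: error_metrics(I, R)["rmse"],
    "mae": lambda I, R, L=None: error_metrics(I, R)["mae"],
    "nmse": lambda I, R, L=None: error_metrics(I, R)["nmse"],
    "nmi": lambda I, R, L=None: float(nmi(I, R)),
    "pcc": lambda I, R, L=None: float(pcc(I, R)),
    "lpips": lambda I, R, L=None: float(learned_metric("lpips", I, R)),
    "dists": lambda I, R, L=None: float(learned_metric("dists", I, R)),
}
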