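"""Calibrated image distortions emulating MR synthesis failure modes.

Eleven distortion generators, each a pure function of (image, parameters,
seed): spatial misalignment (translation, elastic deformation), histogram
distortions (gamma high/low, constant intensity shift), MR acquisition
artifacts simulated in k-space (ghosting, stripe artifacts) or image space
(multiplicative bias field), generic degradations (Gaussian noise, Gaussian
blur), and content replacement by hemisphere mirroring (replace_reflect).

Every distortion is available at five increasing strengths through a
:class:`ParameterSchedule`; strength 1 is barely visible, strength 5 clearly
impedes reading the image.  The default schedule is anchored to the one
published value (translation strength 1 = 1% of the image extent, i.e.
2.4 px on a 240×240 slice) and is fully overridable via configuration.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage

from .core import derive_seed, validate_image

__all__ = [
    "DistortionSpec",
    "ParameterSchedule",
    "DEFAULT_SCHEDULE",
    "DISTORTIONS",
    "translate",
    "elastic_deform",
    "gamma_transform",
    "intensity_shift",
    "ghosting",
    "stripes",
    "bias_field",
    "gaussian_noise",
    "gaussian_blur",
    "replace_reflect",
    "apply",
]


# ---------------------------------------------------------------------------
# Spatial transforms
# ---------------------------------------------------------------------------

def translate(image: np.ndarray, fx: float, fy: float) -> np.ndarray:
    """Shift all pixels by (fx·W, fy·H) with bilinear interpolation.

    ``fx``/``fy`` are fractions of the image width/height; vacated border
    pixels are filled with zero.  Positive fractions move content towards
    larger column/row indices.
    """
    img = validate_image(image)
    if abs(fx) >= 0.5 or abs(fy) >= 0.5:
        raise ValueError("translation fractions must satisfy |f| < 0.5")
    h, w = img.shape
    if fx == 0 and fy == 0:
        return img.copy()
    return ndimage.shift(img, (fy * h, fx * w), order=1, mode="constant", cval=0.0)


def elastic_field(shape, grid_n: int, sigma: float, seed: int) -> np.ndarray:
    """Dense (2, H, W) displacement field from a seeded coarse control grid.

    ``grid_n × grid_n`` control points span the image corners; each point is
    displaced by i.i.d. draws from Normal(0, sigma) (pixels) and the dense
    field is the bilinear interpolation of the control displacements.
    """
    if grid_n < 2:
        raise ValueError("elastic deformation needs a grid of at least 2×2 points")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    h, w = shape
    rng = np.random.default_rng(seed)
    control = rng.normal(0.0, sigma, size=(2, grid_n, grid_n))
    rows = np.linspace(0, grid_n - 1, h)
    cols = np.linspace(0, grid_n - 1, w)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    coords = np.stack([rr, cc])
    field = np.empty((2, h, w))
    for axis in range(2):
        field[axis] = ndimage.map_coordinates(
            control[axis], coords.reshape(2, -1), order=1, mode="nearest"
        ).reshape(h, w)
    return field


def elastic_deform(image: np.ndarray, grid_n: int, sigma: float, seed: int) -> np.ndarray:
    """Random smooth deformation from a displaced control-point grid.

    Higher strengths use a larger displacement sigma and a coarser grid
    (fewer control points), producing fewer but larger local deformations.
    ``sigma = 0`` is the identity.
    """
    img = validate_image(image)
    field = elastic_field(img.shape, grid_n, sigma, seed)
    if sigma == 0:
        return img.copy()
    h, w = img.shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    sample = np.stack([rr + field[0], cc + field[1]])
    return ndimage.map_coordinates(
        img, sample.reshape(2, -1), order=1, mode="constant", cval=0.0
    ).reshape(h, w)


# ---------------------------------------------------------------------------
# Histogram distortions
# ---------------------------------------------------------------------------

def gamma_transform(image: np.ndarray, gamma: float) -> np.ndarray:
    """Power-law intensity mapping on a [0, 1]-normalized scale.

    The image is min-max normalized, raised to ``gamma``, and mapped back to
    the original [min, max], so the intensity range is exactly preserved.
    """
    img = validate_image(image)
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        raise ValueError("constant image has no range to gamma-transform")
    unit = (img - lo) / (hi - lo)
    return np.power(unit, gamma) * (hi - lo) + lo


def intensity_shift(image: np.ndarray, c: float) -> np.ndarray:
    """Add ``c · L_I`` (a fraction of the image's own range) to every pixel."""
    img = validate_image(image)
    L = float(img.max() - img.min())
    return img + c * L


# ---------------------------------------------------------------------------
# MR acquisition artifacts
# ---------------------------------------------------------------------------

def ghosting(
    image: np.ndarray,
    n_ghosts: int = 4,
    amplitude: float = 0.2,
    axis: int = 0,
    seed: int | None = None,
) -> np.ndarray:
    """Ghosting: shifted copies of the anatomy from periodic k-space errors.

    Every ``n_ghosts``-th line of the 2-D spectrum along the phase-encode
    ``axis`` (DC line excluded, conjugate-symmetric partners included so the
    output stays real) is attenuated by ``1 − amplitude``, which produces
    ``n_ghosts`` attenuated copies shifted by 1/n_ghosts of the field of
    view.  ``amplitude = 0`` is the identity.
    """
    img = validate_image(image)
    if n_ghosts < 1:
        raise ValueError("n_ghosts must be >= 1")
    if not 0.0 <= amplitude < 1.0:
        raise ValueError("amplitude must lie in [0, 1)")
    n = img.shape[axis]
    idx = np.arange(n)
    lines = (idx % n_ghosts == 0) & (idx != 0)
    lines = lines | lines[(n - idx) % n]  # enforce conjugate symmetry
    factor = np.ones(n)
    factor[lines] = 1.0 - amplitude
    shape = [1, 1]
    shape[axis] = n
    spectrum = np.fft.fft2(img) * factor.reshape(shape)
    return np.real(np.fft.ifft2(spectrum))


def stripes(
    image: np.ndarray,
    freq_loc: tuple[int, int] | None = None,
    amplitude: float = 8.0,
) -> np.ndarray:
    """Stripe artifact: scale one k-space coefficient (and its conjugate).

    ``freq_loc`` is the (row, col) frequency index in the unshifted FFT; the
    default ``(H // 8, W // 6)`` sits off both axes, so the stripes are
    oblique.  ``amplitude = 1`` is the identity.
    """
    img = validate_image(image)
    h, w = img.shape
    if freq_loc is None:
        freq_loc = (h // 8, w // 6)
    u, v = int(freq_loc[0]) % h, int(freq_loc[1]) % w
    if u == 0 and v == 0:
        raise ValueError("stripe frequency must not be the DC component")
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0")
    spectrum = np.fft.fft2(img)
    partner = ((h - u) % h, (w - v) % w)
    spectrum[u, v] *= amplitude
    if partner != (u, v):
        spectrum[partner] *= amplitude
    return np.real(np.fft.ifft2(spectrum))


_BIAS_EXPONENTS = [(i, j) for i in range(4) for j in range(4) if i + j <= 3]


def bias_polynomial(shape, coeffs: np.ndarray) -> np.ndarray:
    """Evaluate the degree-3 2-D polynomial on normalized coords x,y ∈ [−1,1]."""
    h, w = shape
    y = np.linspace(-1.0, 1.0, h)[:, None]
    x = np.linspace(-1.0, 1.0, w)[None, :]
    poly = np.zeros((h, w))
    for c, (i, j) in zip(coeffs, _BIAS_EXPONENTS):
        poly += c * (x**i) * (y**j)
    return poly


def bias_field(
    image: np.ndarray,
    coeffs: np.ndarray | None = None,
    scale: float = 0.3,
    seed: int = 0,
) -> np.ndarray:
    """Multiplicative smooth bias: ``I · exp(scale · P(x, y))``.

    ``P`` is a degree-3 polynomial in normalized coordinates; its 10
    coefficients are drawn once from Uniform(−1, 1) with ``seed`` when not
    supplied.  An all-zero polynomial (or ``scale = 0``) is the identity.
    """
    img = validate_image(image)
    if coeffs is None:
        rng = np.random.default_rng(seed)
        coeffs = rng.uniform(-1.0, 1.0, size=len(_BIAS_EXPONENTS))
    coeffs = np.asarray(coeffs, dtype=np.float64)
    if coeffs.shape != (len(_BIAS_EXPONENTS),):
        raise ValueError(
            f"expected {len(_BIAS_EXPONENTS)} polynomial coefficients "
            f"(degree <= 3), got shape {coeffs.shape}"
        )
    return img * np.exp(scale * bias_polynomial(img.shape, coeffs))


# ---------------------------------------------------------------------------
# Generic degradations
# ---------------------------------------------------------------------------

def gaussian_noise(image: np.ndarray, sigma_frac: float, seed: int = 0) -> np.ndarray:
    """Additive i.i.d. Gaussian noise with sigma = ``sigma_frac · L_I``.

    Specifying the noise level as a fraction of the image's own intensity
    range makes strengths transfer across intensity scales.
    """
    img = validate_image(image)
    if sigma_frac < 0:
        raise ValueError("sigma_frac must be >= 0")
    if sigma_frac == 0:
        return img.copy()
    L = float(img.max() - img.min())
    rng = np.random.default_rng(seed)
    return img + rng.normal(0.0, sigma_frac * L, size=img.shape)


def gaussian_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian convolution with reflecting boundary; sigma = 0 is identity."""
    img = validate_image(image)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return img.copy()
    return ndimage.gaussian_filter(img, sigma, mode="reflect")


# ---------------------------------------------------------------------------
# Content replacement
# ---------------------------------------------------------------------------

def replace_reflect(image: np.ndarray, fraction: float, side: str = "left") -> np.ndarray:
    """Replace a band next to the vertical midline by its mirror image.

    A band of ``round(fraction · W/2)`` columns adjacent to the midline on
    ``side`` is overwritten with the left-right mirror of the corresponding
    band from the other side (column ``W/2 + k`` maps onto ``W/2 − 1 − k``).
    On brain slices with a unilateral tumor this inserts a second tumor into,
    or removes the tumor from, the target hemisphere.
    """
    img = validate_image(image)
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    h, w = img.shape
    half = w // 2
    band = int(round(fraction * half))
    if band == 0:
        return img.copy()
    out = img.copy()
    k = np.arange(band)
    if side == "left":
        out[:, half - 1 - k] = img[:, half + k]
    else:
        out[:, half + k] = img[:, half - 1 - k]
    return out


# ---------------------------------------------------------------------------
# Strength schedules and dispatch
# ---------------------------------------------------------------------------

#: Default per-strength parameters.  Each distortion's controlling magnitude
#: is strictly monotone in strength; translation strength 1 is the published
#: 1% shift (2.4 px on 240×240).
DEFAULT_SCHEDULE: dict[str, dict[int, dict]] = {
    "translation": {
        s: {"fx": f, "fy": f}
        for s, f in zip(range(1, 6), (0.01, 0.02, 0.04, 0.08, 0.16))
    },
    "elastic": {
        s: {"grid_n": g, "sigma": sig}
        for s, (g, sig) in zip(range(1, 6), [(8, 0.5), (7, 1.0), (6, 1.25), (5, 1.6), (4, 2.0)])
    },
    "gamma_high": {s: {"gamma": g} for s, g in zip(range(1, 6), (1.2, 1.5, 2.0, 2.5, 3.0))},
    "gamma_low": {
        s: {"gamma": g} for s, g in zip(range(1, 6), (1 / 1.2, 1 / 1.5, 0.5, 0.4, 1 / 3.0))
    },
    "intensity_shift": {
        s: {"c": c} for s, c in zip(range(1, 6), (0.01, 0.02, 0.05, 0.1, 0.2))
    },
    "ghosting": {
        s: {"n_ghosts": 4, "amplitude": a, "axis": 0}
        for s, a in zip(range(1, 6), (0.05, 0.1, 0.2, 0.35, 0.5))
    },
    "stripes": {
        s: {"amplitude": a} for s, a in zip(range(1, 6), (16.0, 64.0, 256.0, 1024.0, 4096.0))
    },
    "bias_field": {
        s: {"scale": sc} for s, sc in zip(range(1, 6), (0.1, 0.2, 0.4, 0.7, 1.0))
    },
    "gaussian_noise": {
        s: {"sigma_frac": f} for s, f in zip(range(1, 6), (0.005, 0.01, 0.02, 0.035, 0.05))
    },
    "gaussian_blur": {s: {"sigma": sig} for s, sig in zip(range(1, 6), (0.5, 1.0, 2.0, 3.0, 4.0))},
    "replace_reflect": {
        s: {"fraction": f, "side": "left"}
        for s, f in zip(range(1, 6), (0.2, 0.4, 0.6, 0.8, 1.0))
    },
}

#: Scalar magnitude of each distortion's controlling parameter, used to
#: verify that schedules are strictly monotone in strength.
MAGNITUDE: dict[str, Callable[[dict], float]] = {
    "translation": lambda p: abs(p["fx"]) + abs(p["fy"]),
    "elastic": lambda p: p["sigma"],
    "gamma_high": lambda p: p["gamma"] - 1.0,
    "gamma_low": lambda p: 1.0 - p["gamma"],
    "intensity_shift": lambda p: abs(p["c"]),
    "ghosting": lambda p: p["amplitude"],
    "stripes": lambda p: abs(p["amplitude"] - 1.0),
    "bias_field": lambda p: abs(p["scale"]),
    "gaussian_noise": lambda p: p["sigma_frac"],
    "gaussian_blur": lambda p: p["sigma"],
    "replace_reflect": lambda p: p["fraction"],
}

#: Distortions whose generator consumes an RNG seed.
_SEEDED = {"elastic", "bias_field", "gaussian_noise"}

DISTORTIONS: dict[str, Callable] = {
    "translation": translate,
    "elastic": elastic_deform,
    "gamma_high": gamma_transform,
    "gamma_low": gamma_transform,
    "intensity_shift": intensity_shift,
    "ghosting": ghosting,
    "stripes": stripes,
    "bias_field": bias_field,
    "gaussian_noise": gaussian_noise,
    "gaussian_blur": gaussian_blur,
    "replace_reflect": replace_reflect,
}


@dataclass
class ParameterSchedule:
    """Map (distortion name, strength 1–5) → resolved numeric parameters.

    Defaults come from :data:`DEFAULT_SCHEDULE`; ``overrides`` (e.g. parsed
    from a YAML config) are merged per distortion and strength.
    """

    overrides: dict = field(default_factory=dict)

    def resolve(self, name: str, strength: int) -> dict:
        if name not in DEFAULT_SCHEDULE:
            raise ValueError(f"unknown distortion {name!r}")
        if strength not in range(1, 6):
            raise ValueError("strength must be an integer in 1..5")
        params = copy.deepcopy(DEFAULT_SCHEDULE[name][strength])
        over = self.overrides.get(name, {})
        params.update(over.get(strength, over.get(str(strength), {})))
        return params

    def magnitudes(self, name: str) -> list[float]:
        return [MAGNITUDE[name](self.resolve(name, s)) for s in range(1, 6)]


@dataclass(frozen=True)
class DistortionSpec:
    """Fully determined distortion: name + strength + params + seed.

    The same spec applied to the same image yields a bit-identical output.
    ``params = None`` means "resolve from the schedule".
    """

    name: str
    strength: int
    params: tuple | None = None  # tuple(sorted(dict.items())) for hashability
    seed: int = 0

    def resolved_params(self, schedule: ParameterSchedule | None = None) -> dict:
        if self.params is not None:
            return dict(self.params)
        return (schedule or ParameterSchedule()).resolve(self.name, self.strength)


def apply(
    spec: DistortionSpec,
    image: np.ndarray,
    schedule: ParameterSchedule | None = None,
) -> np.ndarray:
    """Dispatch a spec to its generator with resolved parameters and seed."""
    if spec.name not in DISTORTIONS:
        raise ValueError(f"unknown distortion {spec.name!r}")
    params = spec.resolved_params(schedule)
    if spec.name in _SEEDED:
        params.setdefault("seed", spec.seed)
    return DISTORTIONS[spec.name](image, **params)


def spec_seed(global_seed: int, image_id: str, name: str, strength: int) -> int:
    """Per-grid-cell seed: reproducible yet varying across the benchmark grid."""
    return derive_seed(global_seed, image_id, name, strength)
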