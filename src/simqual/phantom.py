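"""Seeded 2-D brain-like phantom generator with tumor label masks.

Generates synthetic axial slices that emulate the properties of
skull-stripped, atlas-registered T1-weighted contrast-enhanced brain MR
slices: a 240×240 field of view with an exactly-zero background, an
elliptical head region containing two to three tissue compartments (giving
a bimodal foreground histogram), a large float intensity range (default
[0, 1500] to exercise non-8-bit code paths), and an optional glioma-like
tumor of three nested classes (whole tumor ⊇ tumor core ⊇ enhancing tumor)
placed in exactly one hemisphere.

Ground-truth masks are derived analytically from the placed shapes, so the
Dice pipeline is testable without a segmentation model.  The same spec and
seed always produce a bit-identical (image, mask) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import derive_seed, write_image, write_table

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic brain slice.

    ``intensity_range`` sets the approximate foreground span in arbitrary
    units; ``tumor_radius`` is the whole-tumor radius in pixels and must fit
    inside a hemisphere of the head ellipse.
    """

    size: tuple[int, int] = (240, 240)
    intensity_range: tuple[float, float] = (0.0, 1500.0)
    tumor: bool = True
    hemisphere: str = "right"  # side carrying the tumor
    tumor_radius: float | None = None  # default: 7.5% of min(H, W)
    noise_level: float = 0.02  # texture noise sigma as fraction of the range
    smoothing: float = 1.0  # pre-noise Gaussian sigma in pixels
    seed: int = 0


def _ellipse(shape, center, semi_axes, angle: float = 0.0) -> np.ndarray:
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dy = rr - center[0]
    dx = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    return (u / semi_axes[1]) ** 2 + (v / semi_axes[0]) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec = PhantomSpec()):
    """Generate one (image, label mask) pair from a spec.

    The mask holds 0 = background/healthy, and the most specific tumor
    class per pixel: 1 = whole-tumor rim, 2 = tumor core rim, 3 = enhancing
    tumor; the three regions are concentric, so the class-``c``-and-above
    set is nested for increasing ``c``.
    """
    h, w = spec.size
    lo, hi = spec.intensity_range
    if hi <= lo:
        raise ValueError("intensity range must satisfy lo < hi")
    if spec.hemisphere not in ("left", "right"):
        raise ValueError("hemisphere must be 'left' or 'right'")
    rng = np.random.default_rng(spec.seed)
    span = hi - lo

    center = (h / 2 + rng.uniform(-4, 4), w / 2 + rng.uniform(-4, 4))
    head_axes = (h * 0.40 * rng.uniform(0.95, 1.05), w * 0.34 * rng.uniform(0.95, 1.05))
    head = _ellipse((h, w), center, head_axes)

    # tissue compartments: outer "gray matter" shell, inner "white matter"
    # core, small dark ventricles -> bimodal foreground histogram
    inner = _ellipse((h, w), center, (head_axes[0] * 0.62, head_axes[1] * 0.62),
                     angle=rng.uniform(-0.3, 0.3))
    ventricle = _ellipse((h, w), (center[0], center[1]), (head_axes[0] * 0.16, head_axes[1] * 0.10))

    img = np.zeros((h, w))
    img[head] = lo + 0.38 * span * rng.uniform(0.95, 1.05)
    img[inner & head] = lo + 0.66 * span * rng.uniform(0.95, 1.05)
    img[ventricle & head] = lo + 0.17 * span * rng.uniform(0.9, 1.1)

    mask = np.zeros((h, w), dtype=np.int64)
    if spec.tumor:
        side = 1.0 if spec.hemisphere == "right" else -1.0
        r = spec.tumor_radius if spec.tumor_radius is not None else 0.075 * min(h, w)
        offset = head_axes[1] * rng.uniform(0.4, 0.7)
        max_fit = head_axes[1] * 0.45
        if r > max_fit:
            raise ValueError(
                f"tumor radius {r} exceeds the hemisphere "
                f"capacity ({max_fit:.1f} px)"
            )
        t_center = (
            center[0] + rng.uniform(-0.2, 0.2) * head_axes[0],
            center[1] + side * offset,
        )
        whole = _ellipse((h, w), t_center, (r, r * rng.uniform(0.8, 1.0)))
        core = _ellipse((h, w), t_center, (r * 0.65, r * 0.65))
        enhancing = _ellipse((h, w), t_center, (r * 0.35, r * 0.35))
        whole &= head
        core &= whole
        enhancing &= core
        img[whole] = lo + 0.52 * span
        img[core] = lo + 0.30 * span
        img[enhancing] = lo + 0.92 * span  # contrast enhancement: brightest
        mask[whole] = 1
        mask[core] = 2
        mask[enhancing] = 3

    if spec.smoothing > 0:
        img = ndimage.gaussian_filter(img, spec.smoothing, mode="constant")
    if spec.noise_level > 0:
        img = img + rng.normal(0.0, spec.noise_level * span, size=img.shape) * head
    img[~head] = 0.0  # background exactly zero, as after skull-stripping
    np.clip(img, 0.0, None, out=img)
    return img, mask


def generate_dataset(
    n: int,
    base_seed: int = 0,
    template: PhantomSpec = PhantomSpec(),
    out_dir: str | Path | None = None,
):
    """Generate ``n`` phantoms with per-item seeds derived from ``base_seed``.

    Tumor laterality is randomized per item.  If ``out_dir`` is given, each
    image and mask is written as NIfTI together with an ``index.csv``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(derive_seed(base_seed, "laterality"))
    items = []
    index = []
    for i in range(n):
        spec = PhantomSpec(
            size=template.size,
            intensity_range=template.intensity_range,
            tumor=template.tumor,
            hemisphere=rng.choice(["left", "right"]),
            tumor_radius=template.tumor_radius,
            noise_level=template.noise_level,
            smoothing=template.smoothing,
            seed=derive_seed(base_seed, "phantom", i),
        )
        image, mask = generate_phantom(spec)
        items.append((image, mask))
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            img_path = out / f"phantom_{i:03d}.nii.gz"
            msk_path = out / f"phantom_{i:03d}_mask.nii.gz"
            write_image(image, img_path)
            write_image(mask.astype(float), msk_path)
            index.append(
                {"id": f"phantom_{i:03d}", "image": img_path.name,
                 "mask": msk_path.name, "seed": spec.seed,
                 "hemisphere": spec.hemisphere}
            )
    if out_dir is not None and index:
        write_table(index, Path(out_dir) / "index.csv")
    return items
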