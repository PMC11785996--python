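"""Shared image types, data-range computation and file I/O.

The universal currency of the package is a 2-D float array of real
intensities (rows × cols, row 0 at the top).  MR slices are real-valued with
a potentially large, non-standard intensity range; most classical metrics
were designed for 8-bit integers, so a *data range* scalar ``L`` (max − min
over one image, an image pair, or a whole dataset) is threaded through every
metric that has internal constants or thresholds.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DataRange",
    "MIN_IMAGE_SIZE",
    "as_float_image",
    "validate_image",
    "data_range",
    "extract_center_slice",
    "read_image",
    "read_volume",
    "write_image",
    "write_table",
    "derive_seed",
]

#: Minimum in-plane size accepted by the metric operations.
MIN_IMAGE_SIZE = 8


class ImageError(ValueError):
    """Raised for invalid image input (wrong shape, NaN/Inf, too small)."""


@dataclass(frozen=True)
class DataRange:
    """Intensity span ``L`` with the scope it was computed over.

    scope is one of ``"single"``, ``"pair"``, ``"dataset"``.  For images
    drawn from a common dataset the spans nest:
    ``L_single <= L_pair <= L_dataset``.
    """

    L: float
    scope: str = "single"

    def __post_init__(self) -> None:
        if self.L < 0:
            raise ValueError("data range must be nonnegative")
        if self.scope not in ("single", "pair", "dataset"):
            raise ValueError(f"unknown data-range scope {self.scope!r}")

    def __float__(self) -> float:
        return float(self.L)


def as_float_image(image: np.ndarray) -> np.ndarray:
    """Return ``image`` as a C-contiguous float64 2-D array (no validation)."""
    arr = np.asarray(image, dtype=np.float64)
    return np.ascontiguousarray(arr)


def validate_image(image: np.ndarray, *, min_size: int = MIN_IMAGE_SIZE) -> np.ndarray:
    """Validate a 2-D image for metric use and return it as float64.

    Rejects non-2-D input, images smaller than ``min_size`` in either
    dimension, and any non-finite value.  NaN is rejected at this boundary
    rather than propagated: metrics silently corrupt under NaN.
    """
    arr = as_float_image(image)
    if arr.ndim != 2:
        raise ImageError(f"expected a 2-D image, got ndim={arr.ndim}")
    if arr.shape[0] < min_size or arr.shape[1] < min_size:
        raise ImageError(
            f"image {arr.shape} is smaller than the minimum {min_size}×{min_size}"
        )
    if not np.all(np.isfinite(arr)):
        raise ImageError("image contains NaN or Inf values")
    return arr


def _coerce_scope(n_images: int, scope: str | None) -> str:
    if scope is not None:
        return scope
    return {1: "single", 2: "pair"}.get(n_images, "dataset")


def data_range(*images: np.ndarray, scope: str | None = None) -> DataRange:
    """Joint intensity span ``L = max − min`` over the supplied images.

    With one image this is ``L_I``, with two ``L_{I,R}`` (symmetric in the
    order of the images), with more the dataset span ``L_D``.  ``scope`` is
    inferred from the number of images unless given explicitly.
    """
    if not images:
        raise ValueError("data_range requires at least one image")
    lo = np.inf
    hi = -np.inf
    for img in images:
        arr = np.asarray(img, dtype=np.float64)
        if arr.size == 0:
            raise ValueError("data_range received an empty image")
        if not np.all(np.isfinite(arr)):
            raise ImageError("image contains NaN or Inf values")
        lo = min(lo, float(arr.min()))
        hi = max(hi, float(arr.max()))
    return DataRange(L=hi - lo, scope=_coerce_scope(len(images), scope))


def require_positive_range(L: float | DataRange) -> float:
    """Return ``float(L)``, rejecting the degenerate constant-image case."""
    value = float(L)
    if value <= 0:
        raise ValueError("data range L must be > 0 (constant input)")
    return value


def extract_center_slice(volume: np.ndarray) -> np.ndarray:
    """Extract the centered axial 2-D slice of a 3-D volume.

    The slice index along the last (depth) axis is ``floor(depth / 2)``.
    """
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ImageError(f"expected a 3-D volume, got ndim={vol.ndim}")
    depth = vol.shape[-1]
    if depth < 1:
        raise ImageError("volume has zero depth")
    return as_float_image(vol[..., depth // 2])


# ---------------------------------------------------------------------------
# File I/O: NIfTI for float images/volumes, PNG for 8-bit, CSV for tables
# ---------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_PNG_SUFFIXES = (".png",)


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_volume(path: str | Path) -> np.ndarray:
    """Read a NIfTI file as a float array of whatever dimensionality it has."""
    import nibabel as nib

    path = Path(path)
    if not _is_nifti(path):
        raise ValueError(f"unknown volume format: {path.name}")
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64)


def read_image(path: str | Path) -> np.ndarray:
    """Read a 2-D image from NIfTI or PNG.

    3-D NIfTI input is reduced to its center slice; PNG is returned as the
    stored 8-bit integers cast to float.
    """
    path = Path(path)
    if _is_nifti(path):
        data = read_volume(path)
        if data.ndim == 3:
            return extract_center_slice(data)
        if data.ndim != 2:
            raise ImageError(f"cannot interpret {data.ndim}-D NIfTI as an image")
        return as_float_image(data)
    if path.suffix.lower() in _PNG_SUFFIXES:
        import imageio.v3 as iio

        data = iio.imread(path)
        if data.ndim == 3:  # collapse identical RGB channels
            data = data[..., 0]
        return as_float_image(data)
    raise ValueError(f"unknown image format: {path.name}")


def write_image(image: np.ndarray, path: str | Path) -> Path:
    """Write an image as NIfTI (float32) or PNG (8-bit integer data only)."""
    path = Path(path)
    arr = np.asarray(image)
    if _is_nifti(path):
        import nibabel as nib

        nifti = nib.Nifti1Image(arr.astype(np.float32), affine=np.eye(4))
        nib.save(nifti, str(path))
        return path
    if path.suffix.lower() in _PNG_SUFFIXES:
        import imageio.v3 as iio

        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError(
                    "PNG write requires integer data in [0, 255]; "
                    "bin the image explicitly first"
                )
            arr = np.round(arr).astype(np.int64)
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("PNG write requires values in [0, 255]")
        iio.imwrite(path, arr.astype(np.uint8))
        return path
    raise ValueError(f"unknown image format: {path.name}")


def write_table(records: Iterable, path: str | Path) -> Path:
    """Write records (dataclasses or mappings) as a UTF-8 CSV with header."""
    rows = []
    for rec in records:
        if hasattr(rec, "__dataclass_fields__"):
            rows.append(asdict(rec))
        else:
            rows.append(dict(rec))
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if not rows:
            return path
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return path


def derive_seed(*parts) -> int:
    """Derive a stable sub-seed (< 2**31) from arbitrary hashable parts.

    Used to give every (image, distortion, strength) grid cell its own
    reproducible RNG stream from one global seed.
    """
    import zlib

    text = "|".join(str(p) for p in parts)
    return zlib.crc32(text.encode("utf-8")) % (2**31)
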