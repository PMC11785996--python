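"""Downstream-task evaluation: Dice overlap between label masks.

Image synthesis can be judged by how a subsequent task (here: tumor
segmentation) behaves on the synthetic image versus the reference.  This
module scores that comparison with the Dice Similarity Coefficient on
paired integer label masks; producing the masks (i.e. running a
segmentation model) is outside this package's scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["DiceReport", "dice"]


@dataclass(frozen=True)
class DiceReport:
    """Per-class Dice scores plus the foreground (union of classes) score."""

    per_class: dict[int, float]
    foreground: float


def _binary_dice(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        # perfect agreement on absence
        return 1.0
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (na + nb)


def dice(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    classes: Sequence[int] = (1, 2, 3),
) -> DiceReport:
    """Dice Similarity Coefficient per class and on the foreground union.

    ``DSC_c = 2 |A_c ∩ B_c| / (|A_c| + |B_c|)`` where ``A_c`` is the pixel
    set with label ``c``; the foreground score uses the union of all
    non-background classes.  Symmetric in (A, B); a class absent from both
    masks scores 1 (agreement on absence), absent from exactly one scores 0.
    """
    A = np.asarray(mask_a)
    B = np.asarray(mask_b)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    if np.any(A < 0) or np.any(B < 0):
        raise ValueError("label masks must contain nonnegative integers")
    per_class = {int(c): _binary_dice(A == c, B == c) for c in classes}
    fg = _binary_dice(np.isin(A, classes), np.isin(B, classes))
    return DiceReport(per_class=per_class, foreground=fg)
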