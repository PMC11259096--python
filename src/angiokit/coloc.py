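"""Binary-mask colocalization between a vessel channel and a protein stain.

The overlap statistic is the voxel-wise product of two binarized channels:
``n_intersection = sum(A * B)``. Because the denominator convention is a
genuine ambiguity in this kind of analysis, all three normalizations are
always computed — over the vessel mask A, over the protein mask B, and the
Jaccard index — with the headline "degree of overlap" defaulting to the
fraction of vessel voxels also positive for the protein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import BinaryStack
from .stacks import ImageStack

__all__ = ["OverlapResult", "average_intensity", "overlap"]


@dataclass(frozen=True)
class OverlapResult:
    n_A: int
    n_B: int
    n_intersection: int
    fraction_over_A: float
    fraction_over_B: float
    jaccard: float
    mode: str = "over_A"

    @property
    def degree_of_overlap(self) -> float:
        return {
            "over_A": self.fraction_over_A,
            "over_B": self.fraction_over_B,
            "jaccard": self.jaccard,
        }[self.mode]

    def to_dict(self) -> dict:
        return {
            "n_A": self.n_A,
            "n_B": self.n_B,
            "n_intersection": self.n_intersection,
            "fraction_over_A": self.fraction_over_A,
            "fraction_over_B": self.fraction_over_B,
            "jaccard": self.jaccard,
            "mode": self.mode,
            "degree_of_overlap": self.degree_of_overlap,
        }


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, BinaryStack):
        return mask.voxels
    return np.asarray(mask, dtype=bool)


def average_intensity(stack: ImageStack, mask=None) -> float:
    """Mean intensity over the whole stack or over a same-shape mask."""
    vox = np.asarray(stack.voxels, dtype=float)
    if mask is None:
        return float(vox.mean())
    m = _as_bool(mask)
    if m.shape != vox.shape:
        raise ValueError("mask shape does not match stack")
    n = int(m.sum())
    if n == 0:
        raise ValueError("mask is empty")
    return float(vox[m].mean())


def overlap(mask_a, mask_b, mode: str = "over_A") -> OverlapResult:
    """Voxel-count overlap of two binary masks (A = vessel, B = protein)."""
    a = _as_bool(mask_a)
    b = _as_bool(mask_b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    n_a = int(a.sum())
    n_b = int(b.sum())
    n_int = int((a & b).sum())
    if n_a == 0:
        raise ValueError("mask A is empty; fraction over A undefined")
    union = n_a + n_b - n_int
    return OverlapResult(
        n_A=n_a,
        n_B=n_b,
        n_intersection=n_int,
        fraction_over_A=n_int / n_a,
        fraction_over_B=(n_int / n_b) if n_b else 0.0,
        jaccard=(n_int / union) if union else 0.0,
        mode=mode,
    )
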