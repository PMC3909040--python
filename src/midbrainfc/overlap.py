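"""Voxel-set overlap quantification and regional proportion tests.

Thresholded statistical maps become :class:`VoxelSet` objects (sets of 3D
voxel indices with provenance). This module computes Venn-style overlap
counts and integer percentages between two sets, splits the caudate into
head/body versus tail at a coronal world-coordinate boundary, and tests
whether the overlap proportion differs between two regions with a 2x2
Pearson chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "VoxelSet",
    "OverlapResult",
    "ChiSquareResult",
    "overlap_counts",
    "overlap_percent",
    "split_caudate",
    "chi_square_overlap",
]


@dataclass
class VoxelSet:
    """A set of 3D voxel indices surviving a statistical threshold.

    ``voxels`` is an (n, 3) integer array of 0-based indices, unique and
    within ``shape``. ``provenance`` records how the set was produced
    (contrast, threshold, correction, mask).
    """

    voxels: np.ndarray
    shape: tuple[int, int, int]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=int).reshape(-1, 3)
        if v.size:
            if v.min() < 0 or np.any(v >= np.asarray(self.shape)):
                raise ValueError("voxel indices fall outside the grid")
            order = np.lexsort(v.T[::-1])
            v = v[order]
            if len(np.unique(v, axis=0)) != len(v):
                raise ValueError("voxel indices must be unique")
        self.voxels = v
        self.shape = tuple(int(s) for s in self.shape)

    def __len__(self) -> int:
        return self.voxels.shape[0]

    @classmethod
    def from_mask(cls, mask: np.ndarray, provenance: Mapping[str, object] | None = None
                  ) -> "VoxelSet":
        mask = np.asarray(mask, dtype=bool)
        return cls(voxels=np.argwhere(mask), shape=mask.shape,
                   provenance=dict(provenance or {}))

    def to_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        if len(self):
            mask[tuple(self.voxels.T)] = True
        return mask

    def restricted_to(self, mask: np.ndarray) -> "VoxelSet":
        return VoxelSet.from_mask(self.to_mask() & np.asarray(mask, dtype=bool),
                                  provenance=dict(self.provenance))


@dataclass(frozen=True)
class OverlapResult:
    """Venn counts of two voxel sets, with A as the reference set.

    ``percent_of_a`` is round-half-away-from-zero of
    100 * n_intersection / (n_intersection + n_only_a), or None when A is
    empty.
    """

    n_only_a: int
    n_only_b: int
    n_intersection: int
    percent_of_a: int | None


@dataclass(frozen=True)
class ChiSquareResult:
    """2x2 proportion test result; ``higher_region`` is 1 or 2."""

    chi2: float
    p: float
    df: int
    higher_region: int
    proportions: tuple[float, float]


def overlap_counts(set_a: VoxelSet, set_b: VoxelSet) -> OverlapResult:
    """Exact Venn counts between two voxel sets on a common grid."""
    if set_a.shape != set_b.shape:
        raise ValueError(f"grid mismatch: {set_a.shape} vs {set_b.shape}")
    a = set_a.to_mask()
    b = set_b.to_mask()
    inter = int((a & b).sum())
    only_a = int((a & ~b).sum())
    only_b = int((b & ~a).sum())
    total_a = inter + only_a
    percent = overlap_percent(inter, total_a) if total_a > 0 else None
    return OverlapResult(n_only_a=only_a, n_only_b=only_b,
                         n_intersection=inter, percent_of_a=percent)


def overlap_percent(n_intersection: int, n_total: int) -> int:
    """Integer percentage, rounded half away from zero (122/955 -> 13, 4/28 -> 14)."""
    if n_total < 1:
        raise ValueError("n_total must be at least 1")
    if not 0 <= n_intersection <= n_total:
        raise ValueError("need 0 <= n_intersection <= n_total")
    return int(np.floor(100.0 * n_intersection / n_total + 0.5))


def split_caudate(caudate_mask: np.ndarray, affine: np.ndarray,
                  y_boundary_mm: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Split a caudate mask at a coronal world-coordinate boundary.

    A voxel belongs to the head/body iff its world y coordinate is strictly
    greater than ``y_boundary_mm`` (anterior); all other caudate voxels,
    including any exactly on the boundary, form the tail. The two masks
    partition the input.
    """
    caudate_mask = np.asarray(caudate_mask, dtype=bool)
    affine = np.asarray(affine, dtype=float)
    if not caudate_mask.any():
        raise ValueError("caudate mask is empty")
    if affine.shape != (4, 4) or np.isclose(np.linalg.det(affine[:3, :3]), 0.0):
        raise ValueError("affine must be an invertible 4x4 voxel-to-world map")
    idx = np.argwhere(caudate_mask)
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    anterior = world[:, 1] > y_boundary_mm
    headbody = np.zeros_like(caudate_mask)
    tail = np.zeros_like(caudate_mask)
    headbody[tuple(idx[anterior].T)] = True
    tail[tuple(idx[~anterior].T)] = True
    return headbody, tail


def chi_square_overlap(region1_counts: tuple[int, int],
                       region2_counts: tuple[int, int],
                       yates: bool = False) -> ChiSquareResult:
    """Pearson chi-square (df=1) comparing overlap proportions of two regions.

    Each region contributes (overlap, non_overlap) counts; the statistic is
    the standard 2x2 chi-square N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)),
    without continuity correction by default (``yates`` enables it).
    """
    a, b = (int(v) for v in region1_counts)
    c, d = (int(v) for v in region2_counts)
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n1, n2 = a + b, c + d
    if n1 < 1 or n2 < 1:
        raise ValueError("both region totals must be at least 1")
    col1, col2 = a + c, b + d
    if col1 == 0 or col2 == 0:
        raise ValueError("a marginal total is zero; the chi-square is undefined")
    n = n1 + n2
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    chi2 = n * diff ** 2 / (n1 * n2 * col1 * col2)
    p = float(stats.chi2.sf(chi2, df=1))
    p1, p2 = a / n1, c / n2
    return ChiSquareResult(chi2=float(chi2), p=p, df=1,
                           higher_region=1 if p1 >= p2 else 2,
                           proportions=(p1, p2))
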