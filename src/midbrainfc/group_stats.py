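"""Voxelwise group inference on Fisher-z connectivity maps.

Implements the group-level statistics of the seed-connectivity analysis:

- a one-sample t map of z values across maps (overall connectivity);
- the drug-by-span interaction ("inverted-U" quadratic contrast): the
  design crosses a within-subject factor (placebo vs bromocriptine) with a
  between-subject factor (low vs high working-memory span), so the
  interaction is tested exactly as a two-sample t on per-subject paired
  session differences d = z(drug) - z(placebo), low vs high span, with
  pooled variance and df = n_low + n_high - 2; with the default contrast
  weights (-0.5, 0.5, 0.5, -0.5) on the four cell means the contrast
  estimate equals (mean d_low - mean d_high) / 2 and a positive sign means
  the inverted-U pattern (drug helps low span, hurts high span);
- Benjamini-Hochberg FDR, optionally restricted to a small anatomical
  volume, followed by cluster-extent filtering;
- span-connectivity Pearson correlations and the Fisher z test comparing
  two independent correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, stats

from .connectivity import ConnectivityMap
from .overlap import VoxelSet
from .synthetic import CELL_NAMES, CohortDesign, cell_index

__all__ = [
    "ContrastSpec",
    "StatMap",
    "ThresholdSpec",
    "one_sample_t_map",
    "interaction_contrast_map",
    "bh_fdr",
    "small_volume_threshold",
    "uncorrected_threshold",
    "cluster_filter",
    "correlate_with_span",
    "compare_correlations",
    "assign_span_groups",
]

logger = logging.getLogger(__name__)

_CONNECTIVITY_STRUCTS = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class ContrastSpec:
    """Weights over the four design cells in canonical order; must sum to 0."""

    weights: tuple[float, float, float, float] = (-0.5, 0.5, 0.5, -0.5)
    name: str = "invertedU"

    def __post_init__(self) -> None:
        if len(self.weights) != 4:
            raise ValueError("a 2x2 contrast needs exactly four weights")
        if abs(sum(self.weights)) > 1e-12:
            raise ValueError(f"contrast weights must sum to 0, got {self.weights}")


@dataclass
class StatMap:
    """3D statistic and p-value maps with df, validity, and provenance."""

    stat: np.ndarray
    p: np.ndarray
    df: int
    valid: np.ndarray
    contrast: str = ""
    effect: np.ndarray | None = None  # contrast estimate map, when applicable

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.df <= 0:
            raise ValueError("df must be positive")
        pv = np.asarray(self.p)[self.valid]
        if pv.size and (pv.min() < 0 or pv.max() > 1):
            raise ValueError("p values must lie in [0, 1] on valid voxels")


@dataclass(frozen=True)
class ThresholdSpec:
    """FDR level, optional small-volume mask, and cluster-extent settings."""

    q: float = 0.05
    small_volume_mask: np.ndarray | None = None
    min_cluster: int = 20
    cluster_connectivity: int = 6
    direction: str = "both"  # 'both' | 'positive' | 'negative'
    mask_name: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"FDR level q must lie in (0, 1), got {self.q}")
        if self.min_cluster < 1:
            raise ValueError("min_cluster must be at least 1")
        if self.cluster_connectivity not in _CONNECTIVITY_STRUCTS:
            raise ValueError(f"cluster connectivity must be one of {sorted(_CONNECTIVITY_STRUCTS)}")
        if self.direction not in ("both", "positive", "negative"):
            raise ValueError(f"unknown direction {self.direction!r}")


def _stack_maps(maps: Sequence[ConnectivityMap]) -> tuple[np.ndarray, np.ndarray]:
    shapes = {m.z.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"maps are on different grids: {shapes}")
    z = np.stack([m.z for m in maps])
    valid = np.logical_and.reduce([m.valid for m in maps])
    return z, valid


def one_sample_t_map(maps: Sequence[ConnectivityMap],
                     subject_mean: bool = False) -> StatMap:
    """Voxelwise one-sample t of Fisher z values against zero.

    Each map counts as one observation (both sessions of a subject enter
    independently, following the original analysis); ``subject_mean=True``
    first averages a subject's sessions, which respects the within-subject
    dependence at the cost of halving the observation count. Voxels invalid
    in any map, or with zero sample variance, are invalid in the output.
    """
    if subject_mean:
        by_subject: dict[str, list[ConnectivityMap]] = {}
        for m in maps:
            by_subject.setdefault(str(m.subject_id), []).append(m)
        averaged = []
        for sid, ms in sorted(by_subject.items()):
            z, valid = _stack_maps(ms)
            averaged.append(ConnectivityMap(z=z.mean(axis=0), valid=valid, subject_id=sid))
        maps = averaged
    if len(maps) < 3:
        raise ValueError(f"need at least 3 maps, got {len(maps)}")
    z, valid = _stack_maps(maps)
    m = z.shape[0]
    mean = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    degenerate = valid & (sd == 0)
    if np.any(degenerate):
        logger.warning("one_sample_t_map: %d voxel(s) with zero sample variance marked invalid",
                       int(degenerate.sum()))
        valid = valid & ~degenerate
    df = m - 1
    t = np.zeros_like(mean)
    np.divide(mean, sd / np.sqrt(m), out=t, where=valid)
    p = np.ones_like(mean)
    p[valid] = 2.0 * stats.t.sf(np.abs(t[valid]), df)
    return StatMap(stat=t, p=p, df=df, valid=valid, contrast="one_sample_t")


def interaction_contrast_map(maps: Sequence[ConnectivityMap], design: CohortDesign,
                             contrast: ContrastSpec = ContrastSpec()) -> StatMap:
    """Drug-by-span interaction t map from per-subject paired differences.

    Requires both sessions of every subject and at least two subjects per
    span group. The statistic at each voxel is the pooled-variance
    two-sample t comparing d = z(bromocriptine) - z(placebo) between
    low-span and high-span subjects (df = n_low + n_high - 2, two-tailed
    p); its sign is positive for the inverted-U pattern. The ``effect`` map
    holds the contrast weights applied to the four cell means.
    """
    by_subject: dict[str, dict[str, ConnectivityMap]] = {}
    for m in maps:
        by_subject.setdefault(str(m.subject_id), {})[str(m.drug)] = m
    for sid in design.subject_ids:
        sessions = by_subject.get(sid, {})
        if "placebo" not in sessions or "bromocriptine" not in sessions:
            raise ValueError(f"subject {sid} is missing a session "
                             f"(have {sorted(sessions) or 'none'})")
    groups = {g: design.subjects_in_group(g) for g in ("low", "high")}
    for g, members in groups.items():
        if len(members) < 2:
            raise ValueError(f"span group {g!r} has fewer than 2 subjects")

    all_maps = [m for sessions in by_subject.values() for m in sessions.values()]
    _, valid = _stack_maps(all_maps)

    diffs = {g: np.stack([by_subject[s]["bromocriptine"].z - by_subject[s]["placebo"].z
                          for s in members])
             for g, members in groups.items()}
    n1, n2 = len(groups["low"]), len(groups["high"])
    d_low, d_high = diffs["low"], diffs["high"]
    mean_low, mean_high = d_low.mean(axis=0), d_high.mean(axis=0)
    ss_low = ((d_low - mean_low) ** 2).sum(axis=0)
    ss_high = ((d_high - mean_high) ** 2).sum(axis=0)
    df = n1 + n2 - 2
    pooled_var = (ss_low + ss_high) / df
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    degenerate = valid & (se == 0)
    if np.any(degenerate):
        logger.warning("interaction_contrast_map: %d degenerate voxel(s) marked invalid",
                       int(degenerate.sum()))
        valid = valid & ~degenerate
    t = np.zeros_like(mean_low)
    np.divide(mean_low - mean_high, se, out=t, where=valid)
    p = np.ones_like(mean_low)
    p[valid] = 2.0 * stats.t.sf(np.abs(t[valid]), df)

    # Cell means across subject-sessions, combined with the contrast weights.
    cell_sums = np.zeros((4, *mean_low.shape))
    cell_counts = np.zeros(4)
    for sid, sessions in by_subject.items():
        for drug, cmap in sessions.items():
            c = cell_index(design.span_group(sid), drug)
            cell_sums[c] += cmap.z
            cell_counts[c] += 1
    cell_means = cell_sums / cell_counts[:, None, None, None]
    effect = np.tensordot(np.asarray(contrast.weights), cell_means, axes=(0, 0))
    return StatMap(stat=t, p=p, df=df, valid=valid,
                   contrast=f"interaction:{contrast.name}:{contrast.weights}",
                   effect=effect)


def bh_fdr(p_values: Sequence[float], q: float = 0.05
           ) -> tuple[np.ndarray, float | None]:
    """Benjamini-Hochberg step-up procedure.

    Sorts the m p-values ascending, finds the largest i with
    p(i) <= i*q/m, and rejects every hypothesis with p <= p(i). Returns the
    rejected indices (into the input order) and the realized threshold
    p(i), or an empty set and None when nothing is rejected.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("bh_fdr requires at least one p-value")
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p values must be finite and lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must lie in (0, 1), got {q}")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    crit = (np.arange(1, m + 1) * q) / m
    under = np.flatnonzero(sorted_p <= crit)
    if under.size == 0:
        return np.array([], dtype=int), None
    threshold = float(sorted_p[under[-1]])
    rejected = np.flatnonzero(p <= threshold)
    return rejected, threshold


def uncorrected_threshold(stat_map: StatMap, alpha: float = 0.05,
                          mask: np.ndarray | None = None,
                          direction: str = "both") -> VoxelSet:
    """Voxels with p < alpha (no multiplicity correction), optionally signed/masked."""
    keep = stat_map.valid & (stat_map.p < alpha)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    if direction == "positive":
        keep &= stat_map.stat > 0
    elif direction == "negative":
        keep &= stat_map.stat < 0
    elif direction != "both":
        raise ValueError(f"unknown direction {direction!r}")
    return VoxelSet.from_mask(keep, provenance={
        "contrast": stat_map.contrast, "threshold": f"p<{alpha} uncorrected",
        "correction": "none", "direction": direction,
    })


def small_volume_threshold(stat_map: StatMap, spec: ThresholdSpec = ThresholdSpec()
                           ) -> VoxelSet:
    """FDR thresholding restricted to a small volume, then cluster filtering.

    BH-FDR at level ``spec.q`` runs over the p values of the valid voxels
    inside ``spec.small_volume_mask`` (or the whole valid volume when no
    mask is given); degenerate voxels carry no p value and do not count
    toward m. Survivors optionally restricted by sign, then filtered by
    connected-component extent.
    """
    if spec.small_volume_mask is not None:
        mask = np.asarray(spec.small_volume_mask, dtype=bool)
        if mask.shape != stat_map.valid.shape:
            raise ValueError("small-volume mask is not on the statistic map's grid")
        candidates = mask & stat_map.valid
        if not candidates.any():
            raise ValueError("small-volume mask is disjoint from the valid voxels")
    else:
        candidates = stat_map.valid
        if not candidates.any():
            raise ValueError("statistic map has no valid voxels")
    idx = np.argwhere(candidates)
    p = stat_map.p[candidates]
    rejected, threshold = bh_fdr(p, spec.q)
    keep = np.zeros(stat_map.valid.shape, dtype=bool)
    if rejected.size:
        keep[tuple(idx[rejected].T)] = True
    if spec.direction == "positive":
        keep &= stat_map.stat > 0
    elif spec.direction == "negative":
        keep &= stat_map.stat < 0
    provenance = {
        "contrast": stat_map.contrast,
        "correction": "BH-FDR" + (" (small volume)" if spec.small_volume_mask is not None else ""),
        "q": spec.q,
        "realized_threshold": threshold,
        "mask": spec.mask_name,
        "direction": spec.direction,
        "min_cluster": spec.min_cluster,
        "connectivity": spec.cluster_connectivity,
        "m": int(p.size),
    }
    vs = VoxelSet.from_mask(keep, provenance=provenance)
    return cluster_filter(vs, spec.min_cluster, spec.cluster_connectivity)


def cluster_filter(voxels: VoxelSet, min_cluster: int,
                   connectivity: int = 6) -> VoxelSet:
    """Drop connected components smaller than ``min_cluster`` voxels."""
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ValueError(f"unknown connectivity code {connectivity!r}; use one of "
                         f"{sorted(_CONNECTIVITY_STRUCTS)}")
    if min_cluster < 1:
        raise ValueError("min_cluster must be at least 1")
    if min_cluster == 1 or len(voxels) == 0:
        return voxels
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_STRUCTS[connectivity])
    labelled, n_comp = ndimage.label(voxels.to_mask(), structure=structure)
    keep = np.zeros(voxels.shape, dtype=bool)
    if n_comp:
        sizes = np.bincount(labelled.ravel())
        big = np.flatnonzero(sizes >= min_cluster)
        big = big[big > 0]
        keep = np.isin(labelled, big)
    provenance = dict(voxels.provenance)
    provenance.update({"min_cluster": min_cluster, "connectivity": connectivity})
    return VoxelSet.from_mask(keep, provenance=provenance)


def correlate_with_span(per_subject_values: Sequence[float],
                        span_scores: Sequence[float]) -> tuple[float, float, int]:
    """Pearson correlation of per-subject connectivity with span scores.

    Returns (r, two-tailed p, n) with p from t = r sqrt(n-2) / sqrt(1-r^2),
    df = n - 2. A perfect correlation yields p = 0.0 (below the machine
    floor).
    """
    v = np.asarray(per_subject_values, dtype=float).ravel()
    s = np.asarray(span_scores, dtype=float).ravel()
    if v.shape != s.shape:
        raise ValueError("value and score lists must have equal length")
    n = v.size
    if n < 4:
        raise ValueError(f"need at least 4 subjects, got {n}")
    if np.all(s == s[0]):
        raise ValueError("span scores are constant; correlation undefined")
    if np.all(v == v[0]):
        raise ValueError("connectivity values are constant; correlation undefined")
    from .connectivity import pearson_r

    r = pearson_r(v, s)
    if abs(r) >= 1.0:
        return r, 0.0, n
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p, n


def compare_correlations(r1: float, n1: int, r2: float, n2: int
                         ) -> tuple[float, float]:
    """Fisher z test for two independent Pearson correlations.

    Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-tailed
    normal p.
    """
    for r in (r1, r2):
        if not -1.0 < r < 1.0:
            raise ValueError(f"correlations must lie strictly in (-1, 1), got {r}")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError(f"each sample needs n > 3, got {n}")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), p


def assign_span_groups(span_scores: Sequence[float], cutoff: float = 3.5) -> list[str]:
    """Median-split labels: 'high' for scores at or above the cutoff, else 'low'."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return ["high" if s >= cutoff else "low" for s in np.asarray(span_scores, dtype=float)]
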