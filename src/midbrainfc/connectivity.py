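"""Seed-based whole-volume correlation mapping with Fisher z transformation.

The seed region's mean time series is correlated (Pearson) with every voxel
series inside a brain mask; the r map is variance-stabilized with the
Fisher transform z = atanh(r). Voxels whose series have (numerically) zero
variance cannot carry a correlation and are marked invalid in an explicit
validity mask rather than silently zeroed, so downstream group statistics
can exclude them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import BoldRun

__all__ = ["ConnectivityMap", "pearson_r", "fisher_z", "seed_connectivity_map"]

_CLAMP = 1.0 - 1e-7
_VAR_TINY = 1e-12  # relative variance floor below which a series counts as constant


@dataclass
class ConnectivityMap:
    """Per-subject-session 3D map of Fisher z values versus the seed."""

    z: np.ndarray
    valid: np.ndarray
    subject_id: str | None = None
    session: str | None = None
    drug: str | None = None
    seed_name: str = "seed"
    n_timepoints: int | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.z.shape != self.valid.shape:
            raise ValueError("z and valid masks must share a shape")
        if not np.all(np.isfinite(self.z[self.valid])):
            raise ValueError("z must be finite on valid voxels")


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation of two equal-length series."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples for a correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx == 0.0 or vy == 0.0:
        raise ValueError("correlation undefined: an input series has zero variance")
    r = float(xc @ yc) / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


def fisher_z(r, clamp: bool = False):
    """Fisher transform z = atanh(r) = 0.5 ln((1+r)/(1-r)).

    With ``clamp`` enabled, |r| >= 1 is pulled to 1 - 1e-7 (preserving sign)
    and a warning is issued; otherwise such values raise.
    """
    arr = np.asarray(r, dtype=float)
    out_of_range = np.abs(arr) >= 1.0
    if np.any(out_of_range):
        if not clamp:
            raise ValueError("fisher_z requires |r| < 1 (enable clamp to truncate)")
        warnings.warn("clamping |r| >= 1 before Fisher transform", RuntimeWarning,
                      stacklevel=2)
        arr = np.where(out_of_range, np.sign(arr) * _CLAMP, arr)
    z = np.arctanh(arr)
    return float(z) if np.isscalar(r) else z


def seed_connectivity_map(run: BoldRun, seed_mask: np.ndarray, brain_mask: np.ndarray,
                          clamp: bool = True, seed_name: str = "seed") -> ConnectivityMap:
    """Fisher-z correlation of the seed mean series with every brain voxel.

    Zero-variance voxel series are marked invalid. Correlations of exactly
    +/-1 (e.g. a voxel identical to the seed mean) follow the clamp policy:
    clamped with a warning by default, or invalidated when ``clamp=False``.
    """
    seed_mask = np.asarray(seed_mask, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    for name, mask in (("seed", seed_mask), ("brain", brain_mask)):
        if mask.shape != run.shape3d:
            raise ValueError(f"{name} mask shape {mask.shape} does not match run grid {run.shape3d}")
        if not mask.any():
            raise ValueError(f"{name} mask selects no voxels")

    n = run.n_timepoints
    seed_series = run.data[seed_mask].mean(axis=0).astype(float)
    sc = seed_series - seed_series.mean()
    seed_ss = float(sc @ sc)
    if seed_ss == 0.0:
        raise ValueError("seed mean series has zero variance")

    vox = run.data[brain_mask].astype(float)
    vc = vox - vox.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", vc, vc)
    scale = np.max(ss) if ss.size else 1.0
    ok = ss > _VAR_TINY * max(scale, 1.0)

    r = np.zeros(vox.shape[0])
    r[ok] = (vc[ok] @ sc) / np.sqrt(ss[ok] * seed_ss)
    r = np.clip(r, -1.0, 1.0)

    at_bound = ok & (np.abs(r) >= 1.0)
    if np.any(at_bound):
        if clamp:
            warnings.warn(
                f"clamping {int(at_bound.sum())} voxel correlation(s) at |r| = 1",
                RuntimeWarning, stacklevel=2,
            )
            r[at_bound] = np.sign(r[at_bound]) * _CLAMP
        else:
            ok &= ~at_bound

    z = np.zeros(run.shape3d)
    valid = np.zeros(run.shape3d, dtype=bool)
    zr = np.zeros(vox.shape[0])
    zr[ok] = np.arctanh(r[ok])
    z[brain_mask] = zr
    valid[brain_mask] = ok
    return ConnectivityMap(z=z, valid=valid, subject_id=run.subject_id,
                           session=run.session, drug=run.drug,
                           seed_name=seed_name, n_timepoints=n)
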