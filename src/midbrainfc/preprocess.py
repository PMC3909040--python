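"""Temporal and spatial preprocessing of 4D BOLD runs.

The pipeline order mirrors the usual resting-state recipe: band-pass
filtering of every voxel time series, spatial Gaussian smoothing of every
volume, extraction of nuisance time series (white-matter and CSF means)
from the filtered, smoothed data, and voxelwise least-squares removal of
those nuisance series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "BoldRun",
    "FilterBand",
    "bandpass_filter",
    "regress_nuisance",
    "smooth_spatial",
    "extract_mean_timeseries",
    "preprocess_run",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class BoldRun:
    """One subject-session 4D time-series volume with acquisition metadata.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Signal intensity. Stored as float; finite everywhere.
    tr : float
        Repetition time in seconds.
    affine : ndarray, shape (4, 4)
        Voxel-to-world map (homogeneous coordinates, mm).
    subject_id, session, drug : str, optional
        Provenance labels carried through the pipeline.
    """

    data: np.ndarray
    tr: float
    affine: np.ndarray
    subject_id: str | None = None
    session: str | None = None
    drug: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BoldRun data must be 4D (x, y, z, t), got ndim={self.data.ndim}")
        if self.data.shape[3] < 8:
            raise ValueError(f"BoldRun needs at least 8 timepoints, got {self.data.shape[3]}")
        if not self.tr > 0:
            raise ValueError(f"TR must be positive, got {self.tr}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BoldRun data contains non-finite values")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.tr)

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm (norms of the affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def with_data(self, data: np.ndarray) -> "BoldRun":
        return replace(self, data=data)


@dataclass(frozen=True)
class FilterBand:
    """Pass band in Hz; must sit strictly inside (0, Nyquist)."""

    low: float = 0.009
    high: float = 0.08

    def __post_init__(self) -> None:
        if not 0.0 < self.low < self.high:
            raise ValueError(f"need 0 < low < high, got ({self.low}, {self.high})")

    def validate_for_tr(self, tr: float) -> None:
        nyq = 1.0 / (2.0 * tr)
        if self.high >= nyq:
            raise ValueError(
                f"band upper edge {self.high} Hz is at or above Nyquist {nyq} Hz for TR={tr}s"
            )


def _as_band(band: "FilterBand | tuple[float, float]") -> FilterBand:
    if isinstance(band, FilterBand):
        return band
    return FilterBand(*band)


def bandpass_filter(run: BoldRun, band: "FilterBand | tuple[float, float]" = FilterBand(),
                    order: int = 2) -> BoldRun:
    """Zero-phase band-pass filter every voxel time series.

    Each series is mean/linear-trend removed, then filtered with a
    Butterworth band-pass of the given order applied forward-backward
    (``sosfiltfilt``), so the effective magnitude response is the squared
    Butterworth response and the phase is zero.
    """
    band = _as_band(band)
    band.validate_for_tr(run.tr)
    fs = 1.0 / run.tr
    sos = signal.butter(order, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
    flat = run.data.reshape(-1, run.n_timepoints).astype(np.float64)
    flat = signal.detrend(flat, axis=1, type="linear")
    filtered = signal.sosfiltfilt(sos, flat, axis=1)
    return run.with_data(filtered.reshape(run.data.shape).astype(run.data.dtype, copy=False))


def regress_nuisance(run: BoldRun, confound_series: Sequence[np.ndarray],
                     names: Sequence[str] | None = None) -> BoldRun:
    """Remove nuisance time series from every voxel by least squares.

    The design matrix is [intercept, confounds]; the returned run holds the
    residuals, which are orthogonal to every confound column and have zero
    mean. A rank-deficient design raises, naming the collinear columns.
    """
    t = run.n_timepoints
    cols = [np.ones(t)]
    for i, c in enumerate(confound_series):
        c = np.asarray(c, dtype=float).ravel()
        if c.shape[0] != t:
            raise ValueError(f"confound {i} has length {c.shape[0]}, expected {t}")
        cols.append(c)
    X = np.column_stack(cols)
    if names is None:
        names = [f"confound_{i}" for i in range(len(confound_series))]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = _collinear_columns(X, ["intercept", *names])
        raise ValueError(f"nuisance design matrix is rank deficient; collinear columns: {collinear}")
    flat = run.data.reshape(-1, t).astype(np.float64).T  # (t, n_vox)
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    resid = flat - X @ beta
    return run.with_data(resid.T.reshape(run.data.shape).astype(run.data.dtype, copy=False))


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name the columns involved in a rank deficiency (smallest singular directions)."""
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps
    null_dirs = vt[s < tol] if np.any(s < tol) else vt[-1:]
    involved = np.any(np.abs(null_dirs) > 1e-8, axis=0)
    return [n for n, flag in zip(names, involved) if flag]


def smooth_spatial(run: BoldRun, fwhm_mm: float, mode: str = "reflect") -> BoldRun:
    """Volume-wise 3D Gaussian smoothing with an isotropic FWHM in mm.

    Anisotropic voxels are handled with a per-axis sigma in voxel units,
    sigma_axis = fwhm / (voxel_size_axis * 2 sqrt(2 ln 2)). ``fwhm_mm = 0``
    is the identity. Boundary handling defaults to reflection.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm must be non-negative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return run.with_data(run.data.copy())
    sigma_vox = fwhm_mm / (_FWHM_TO_SIGMA * run.voxel_size)
    smoothed = ndimage.gaussian_filter(
        run.data.astype(np.float64), sigma=(*sigma_vox, 0.0), mode=mode
    )
    return run.with_data(smoothed.astype(run.data.dtype, copy=False))


def extract_mean_timeseries(run: BoldRun, mask: np.ndarray) -> np.ndarray:
    """Arithmetic mean over masked voxels at each timepoint."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != run.shape3d:
        raise ValueError(f"mask shape {mask.shape} does not match run grid {run.shape3d}")
    if not mask.any():
        raise ValueError("mask selects no voxels")
    return run.data[mask].mean(axis=0)


def preprocess_run(run: BoldRun, band: "FilterBand | tuple[float, float]" = FilterBand(),
                   fwhm_mm: float = 4.0, wm_mask: np.ndarray | None = None,
                   csf_mask: np.ndarray | None = None, smoothing_mode: str = "reflect") -> BoldRun:
    """Full preprocessing: filter, smooth, then regress WM/CSF means.

    Nuisance series are extracted from the already filtered and smoothed
    data, so the residuals are orthogonal to the nuisance signal as it
    appears in the data entering the correlation stage.
    """
    out = bandpass_filter(run, band)
    out = smooth_spatial(out, fwhm_mm, mode=smoothing_mode)
    confounds: list[np.ndarray] = []
    names: list[str] = []
    if wm_mask is not None:
        confounds.append(extract_mean_timeseries(out, wm_mask))
        names.append("white_matter")
    if csf_mask is not None:
        confounds.append(extract_mean_timeseries(out, csf_mask))
        names.append("csf")
    if confounds:
        out = regress_nuisance(out, confounds, names=names)
    return out
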