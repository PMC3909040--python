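"""Synthetic BOLD phantom cohorts with planted connectivity structure.

Every voxel time series is a linear mixture of three mutually independent,
band-limited, unit-variance components::

    voxel(t) = a * seed(t) + b * confound(t) + sigma_e * noise(t)

so the population Pearson correlation between the seed signal and the voxel
has the closed form a*sigma_s / sqrt(a^2 sigma_s^2 + b^2 sigma_c^2 +
sigma_e^2) (see :func:`planted_correlation`). The generator inverts that
formula to plant an exact population correlation per design cell, which
gives every downstream stage an analytic oracle.

The default phantom emulates the study design it stands in for: 16 subjects
(8 high working-memory span, 8 low), two sessions each (placebo and the
dopamine agonist bromocriptine), TR = 2 s, 150 timepoints (five minutes),
1.8 x 1.8 x 3.45 mm voxels, a midbrain seed, caudate split into head/body
and tail at world y = 2 mm, putamen, ventral striatum, and white-matter /
CSF compartments carrying a shared physiological confound. A contiguous
slab of caudate voxels is given an inverted-U correlation pattern over the
four drug-by-span cells; a surrounding shell is connected to the seed at a
constant level; the remaining caudate voxels are null.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .preprocess import BoldRun

__all__ = [
    "REGION_LABELS",
    "PhantomGeometry",
    "EffectSpec",
    "CohortDesign",
    "GroundTruth",
    "make_phantom_geometry",
    "balanced_cohort_design",
    "simulate_band_limited_signal",
    "planted_correlation",
    "coupling_for_correlation",
    "simulate_cohort",
    "cell_index",
    "CELL_NAMES",
]

# Integer codes of the label volume.
REGION_LABELS: dict[str, int] = {
    "background": 0,
    "midbrain_seed": 1,
    "caudate_headbody": 2,
    "caudate_tail": 3,
    "putamen": 4,
    "ventral_striatum": 5,
    "white_matter": 6,
    "csf": 7,
    "other_brain": 8,
}

# Canonical design-cell order used everywhere downstream.
CELL_NAMES: tuple[str, ...] = (
    "low-placebo",
    "low-bromocriptine",
    "high-placebo",
    "high-bromocriptine",
)

GROUND_TRUTH_CLASSES: dict[str, int] = {
    "dopaminergic_invertedU": 1,
    "connected_constant": 2,
    "null": 3,
}

Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # stop-exclusive per axis

DEFAULT_SHAPE = (18, 24, 10)
DEFAULT_VOXEL_SIZE = (1.8, 1.8, 3.45)
# World y of voxel index j is 1.8*j - 19.8, so the caudate head/body (j>=13)
# sits strictly anterior to the y = 2 mm coronal boundary.
DEFAULT_ORIGIN = (-16.2, -19.8, -17.25)

DEFAULT_REGION_SPEC: dict[str, Box] = {
    "brain": ((1, 17), (1, 23), (1, 9)),
    "midbrain_seed": ((8, 10), (3, 5), (2, 4)),
    "caudate_tail": ((3, 7), (7, 13), (4, 8)),
    "caudate_headbody": ((3, 7), (13, 20), (4, 8)),
    "putamen": ((11, 15), (7, 17), (4, 8)),
    "ventral_striatum": ((8, 11), (15, 19), (2, 4)),
    "white_matter": ((2, 5), (1, 5), (7, 9)),
    "csf": ((13, 16), (1, 5), (7, 9)),
}


def cell_index(span_group: str, drug: str) -> int:
    """Index of a (span group, drug) pair in the canonical cell order."""
    try:
        return CELL_NAMES.index(f"{span_group}-{drug}")
    except ValueError:
        raise ValueError(f"unknown design cell ({span_group!r}, {drug!r})") from None


@dataclass
class PhantomGeometry:
    """3D label grid, voxel-to-world affine, and named region masks."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray
    labels: np.ndarray
    y_boundary_mm: float = 2.0

    def mask(self, name: str) -> np.ndarray:
        if name == "caudate":
            return self.mask("caudate_headbody") | self.mask("caudate_tail")
        if name == "brain":
            return self.labels > 0
        if name not in REGION_LABELS:
            raise KeyError(f"unknown region {name!r}")
        return self.labels == REGION_LABELS[name]

    def region_size(self, name: str) -> int:
        return int(self.mask(name).sum())

    def world_y(self) -> np.ndarray:
        """World y coordinate of every voxel (3D array, mm)."""
        jj = np.arange(self.shape[1])
        y = self.affine[1, 1] * jj + self.affine[1, 3]
        return np.broadcast_to(y[None, :, None], self.shape)


@dataclass(frozen=True)
class EffectSpec:
    """Planted connectivity effect over the 2x2 drug-by-span design.

    ``r_cells`` holds the planted population seed-voxel correlation per
    design cell in canonical order (low-placebo, low-bromocriptine,
    high-placebo, high-bromocriptine) for the dopaminergic caudate voxels.
    ``frac_dopaminergic`` is the target fraction of caudate voxels given the
    inverted-U pattern (realised as the closest whole number of contiguous
    coronal slabs). ``r_constant`` is the correlation of
    connected-but-unmodulated voxels in every cell, ``noise_sd`` the
    residual noise scale, and ``confound_weight`` the coupling of gray
    voxels to the shared physiological confound.
    """

    r_cells: tuple[float, float, float, float] = (0.1, 0.5, 0.5, 0.1)
    frac_dopaminergic: float = 0.25
    r_constant: float = 0.3
    noise_sd: float = 1.0
    confound_weight: float = 0.5

    def __post_init__(self) -> None:
        if len(self.r_cells) != 4:
            raise ValueError("r_cells must hold exactly four values (one per design cell)")
        for name, r in list(zip(CELL_NAMES, self.r_cells)) + [("r_constant", self.r_constant)]:
            if not -1.0 < r < 1.0:
                raise ValueError(f"planted correlation for {name} must lie in (-1, 1), got {r}")
        if not 0.0 <= self.frac_dopaminergic <= 1.0:
            raise ValueError("frac_dopaminergic must lie in [0, 1]")
        if self.noise_sd < 0 or self.confound_weight < 0:
            raise ValueError("noise_sd and confound_weight must be non-negative")

    @property
    def is_inverted_u(self) -> bool:
        """True when the drug helps the low-span cells and hurts the high-span cells."""
        r = self.r_cells
        return r[1] > r[0] and r[2] > r[3]

    @classmethod
    def null(cls, r: float = 0.3, **kwargs) -> "EffectSpec":
        """All four cells share one correlation: no interaction anywhere."""
        return cls(r_cells=(r, r, r, r), **kwargs)


@dataclass
class CohortDesign:
    """Subjects, span scores/groups, and the session-to-drug assignment."""

    subject_ids: tuple[str, ...]
    span_scores: Mapping[str, float]
    drug_by_session: Mapping[str, Mapping[str, str]]
    span_cutoff: float = 3.5

    def __post_init__(self) -> None:
        for sid in self.subject_ids:
            if sid not in self.span_scores:
                raise ValueError(f"subject {sid} has no span score")
            sessions = self.drug_by_session.get(sid)
            if sessions is None or len(sessions) != 2:
                raise ValueError(f"subject {sid} must have exactly two sessions")
            drugs = sorted(sessions.values())
            if drugs != ["bromocriptine", "placebo"]:
                raise ValueError(
                    f"subject {sid} needs one placebo and one bromocriptine session, got {drugs}"
                )

    def span_group(self, subject_id: str) -> str:
        return "high" if self.span_scores[subject_id] >= self.span_cutoff else "low"

    @property
    def span_groups(self) -> dict[str, str]:
        return {s: self.span_group(s) for s in self.subject_ids}

    def subjects_in_group(self, group: str) -> list[str]:
        return [s for s in self.subject_ids if self.span_group(s) == group]

    def iter_runs(self):
        """Yield (subject_id, session, drug) in a stable order."""
        for sid in self.subject_ids:
            for session in sorted(self.drug_by_session[sid]):
                yield sid, session, self.drug_by_session[sid][session]


@dataclass
class GroundTruth:
    """Voxel classes planted in the caudate plus everything needed to replay them."""

    class_map: np.ndarray  # int volume; 0 outside caudate, else GROUND_TRUTH_CLASSES code
    effect: EffectSpec
    rng_seed: int
    couplings: dict

    def mask(self, class_name: str) -> np.ndarray:
        return self.class_map == GROUND_TRUTH_CLASSES[class_name]

    def to_json(self) -> str:
        payload = {
            "shape": list(self.class_map.shape),
            "classes": {
                name: np.argwhere(self.mask(name)).tolist()
                for name in GROUND_TRUTH_CLASSES
            },
            "effect": {
                "r_cells": list(self.effect.r_cells),
                "frac_dopaminergic": self.effect.frac_dopaminergic,
                "r_constant": self.effect.r_constant,
                "noise_sd": self.effect.noise_sd,
                "confound_weight": self.effect.confound_weight,
            },
            "rng_seed": self.rng_seed,
            "couplings": self.couplings,
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        class_map = np.zeros(tuple(payload["shape"]), dtype=np.int16)
        for name, code in GROUND_TRUTH_CLASSES.items():
            idx = np.asarray(payload["classes"][name], dtype=int)
            if idx.size:
                class_map[tuple(idx.T)] = code
        eff = payload["effect"]
        effect = EffectSpec(
            r_cells=tuple(eff["r_cells"]),
            frac_dopaminergic=eff["frac_dopaminergic"],
            r_constant=eff["r_constant"],
            noise_sd=eff["noise_sd"],
            confound_weight=eff["confound_weight"],
        )
        return cls(class_map=class_map, effect=effect,
                   rng_seed=payload["rng_seed"], couplings=payload["couplings"])


def make_phantom_geometry(
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    region_spec: Mapping[str, Box] | None = None,
    origin: tuple[float, float, float] = DEFAULT_ORIGIN,
    y_boundary_mm: float = 2.0,
) -> PhantomGeometry:
    """Build the labelled phantom grid from named box extents.

    ``region_spec`` maps region names to stop-exclusive per-axis index
    ranges; it must contain a ``brain`` box enclosing all named regions.
    Voxels of the brain box not claimed by a named region become
    ``other_brain``. Overlapping named regions raise, naming the pair.
    """
    spec = dict(DEFAULT_REGION_SPEC if region_spec is None else region_spec)
    if "brain" not in spec:
        raise ValueError("region_spec must include a 'brain' box")
    brain_box = spec.pop("brain")

    for name, box in [("brain", brain_box), *spec.items()]:
        for axis, (lo, hi) in enumerate(box):
            if not (0 <= lo < hi <= shape[axis]):
                raise ValueError(f"region {name!r} extent {box} does not fit in shape {shape}")

    labels = np.zeros(shape, dtype=np.int16)
    bsl = tuple(slice(lo, hi) for lo, hi in brain_box)
    labels[bsl] = REGION_LABELS["other_brain"]

    claimed = np.zeros(shape, dtype=bool)
    for name, box in spec.items():
        if name not in REGION_LABELS:
            raise ValueError(f"unknown region name {name!r}")
        sl = tuple(slice(lo, hi) for lo, hi in box)
        region = np.zeros(shape, dtype=bool)
        region[sl] = True
        if np.any(region & claimed):
            other = _find_overlap(spec, name, region, shape)
            raise ValueError(f"regions {name!r} and {other!r} overlap")
        if not np.all(labels[sl] == REGION_LABELS["other_brain"]):
            raise ValueError(f"region {name!r} extends outside the brain box")
        labels[sl] = REGION_LABELS[name]
        claimed |= region

    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = voxel_size
    affine[:3, 3] = origin

    geom = PhantomGeometry(shape=tuple(shape), voxel_size=tuple(voxel_size),
                           affine=affine, labels=labels, y_boundary_mm=y_boundary_mm)

    for name in REGION_LABELS:
        if name != "background" and geom.region_size(name) == 0:
            raise ValueError(f"region {name!r} is empty")

    wy = geom.world_y()
    if np.any(wy[geom.mask("caudate_headbody")] <= y_boundary_mm):
        raise ValueError(f"caudate_headbody voxels must lie anterior to world y = {y_boundary_mm} mm")
    if np.any(wy[geom.mask("caudate_tail")] > y_boundary_mm):
        raise ValueError(f"caudate_tail voxels must lie at or posterior to world y = {y_boundary_mm} mm")
    return geom


def _find_overlap(spec: Mapping[str, Box], name: str, region: np.ndarray,
                  shape: tuple[int, int, int]) -> str:
    for other, box in spec.items():
        if other == name:
            continue
        mask = np.zeros(shape, dtype=bool)
        mask[tuple(slice(lo, hi) for lo, hi in box)] = True
        if np.any(mask & region):
            return other
    return "<unknown>"


def balanced_cohort_design(n_low: int = 8, n_high: int = 8, rng_seed: int = 0,
                           span_cutoff: float = 3.5) -> CohortDesign:
    """A counterbalanced two-session cohort with a median-split span structure.

    Span scores are drawn uniformly on [1.5, 3.4] for low-span subjects and
    [3.5, 5.5] for high-span subjects (the cutoff is inclusive at 3.5).
    Drug order alternates across subjects, so half receive bromocriptine in
    the first session.
    """
    rng = _child_rng(rng_seed, "design")
    ids, scores, sessions = [], {}, {}
    low = rng.uniform(1.5, 3.4, size=n_low)
    high = rng.uniform(3.5, 5.5, size=n_high)
    for i, score in enumerate(np.concatenate([low, high])):
        sid = f"sub-{i + 1:02d}"
        ids.append(sid)
        scores[sid] = float(score)
        first, second = ("placebo", "bromocriptine") if i % 2 == 0 else ("bromocriptine", "placebo")
        sessions[sid] = {"ses-1": first, "ses-2": second}
    return CohortDesign(subject_ids=tuple(ids), span_scores=scores,
                        drug_by_session=sessions, span_cutoff=span_cutoff)


def _child_rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic child stream: seed plus CRC32 of the string keys."""
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(str(k).encode()) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _band_bins(n: int, tr: float, band: tuple[float, float]) -> np.ndarray:
    low, high = band
    nyq = 1.0 / (2.0 * tr)
    if not 0.0 < low < high:
        raise ValueError(f"need 0 < low < high, got {band}")
    if high >= nyq:
        raise ValueError(f"band upper edge {high} Hz is at or above Nyquist {nyq} Hz")
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= low) & (freqs <= high)
    if not keep.any():
        raise ValueError(f"no DFT bins inside band {band} at n={n}, tr={tr}")
    return keep


def _band_limited_matrix(n_series: int, n_timepoints: int, tr: float,
                         band: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Rows are independent zero-mean, unit-variance, strictly band-limited series."""
    keep = _band_bins(n_timepoints, tr, band)
    white = rng.standard_normal((n_series, n_timepoints))
    spectrum = np.fft.rfft(white, axis=1)
    spectrum[:, ~keep] = 0.0
    x = np.fft.irfft(spectrum, n=n_timepoints, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("degenerate band-limited series (zero variance)")
    return x / sd


def simulate_band_limited_signal(n_timepoints: int, tr: float = 2.0,
                                 band: tuple[float, float] = (0.009, 0.08),
                                 rng_seed: "int | np.random.Generator" = 0) -> np.ndarray:
    """One zero-mean, unit-variance series whose spectrum lies inside ``band``.

    Built by masking the DFT of white Gaussian noise to the in-band bins and
    inverting, so spectral control is exact (no filter transients) and the
    periodogram carries essentially all power inside the band.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else _child_rng(rng_seed, "signal")
    return _band_limited_matrix(1, n_timepoints, tr, band, rng)[0]


def planted_correlation(a: float, b: float, sigma_s: float = 1.0,
                        sigma_c: float = 1.0, sigma_e: float = 1.0) -> float:
    """Population Pearson r between seed and voxel under the mixture model.

    For voxel = a*seed + b*confound + noise with independent components,
    r = a*sigma_s / sqrt(a^2 sigma_s^2 + b^2 sigma_c^2 + sigma_e^2).
    """
    var = (a * sigma_s) ** 2 + (b * sigma_c) ** 2 + sigma_e ** 2
    if var == 0:
        raise ValueError("correlation undefined: voxel series has zero variance")
    return a * sigma_s / np.sqrt(var)


def coupling_for_correlation(r: float, b: float, sigma_s: float = 1.0,
                             sigma_c: float = 1.0, sigma_e: float = 1.0) -> float:
    """Invert :func:`planted_correlation` for the seed coupling ``a``."""
    if not -1.0 < r < 1.0:
        raise ValueError(f"target correlation must lie in (-1, 1), got {r}")
    other_var = (b * sigma_c) ** 2 + sigma_e ** 2
    if other_var == 0:
        if r == 0.0:
            return 0.0
        raise ValueError(
            f"correlation {r} unreachable: with no confound or noise the correlation is 0 or +/-1"
        )
    if sigma_s == 0:
        raise ValueError("seed signal has zero variance")
    return r / sigma_s * np.sqrt(other_var / (1.0 - r * r))


def _assign_ground_truth(geometry: PhantomGeometry, effect: EffectSpec,
                         rng_seed: int) -> GroundTruth:
    """Plant voxel classes in the caudate as contiguous coronal slabs.

    The inverted-U class occupies the central slab (the whole-number of
    coronal slices closest to ``frac_dopaminergic`` of the caudate); a shell
    of up to two slices on each side is connected at a constant level; the
    remaining caudate voxels are null. Contiguity keeps the planted effect
    compact under spatial smoothing and cluster-extent thresholding, which
    is how a dopaminergic territory would present in real data.
    """
    caudate = geometry.mask("caudate")
    ys = np.unique(np.argwhere(caudate)[:, 1])
    n_y = len(ys)
    k = int(np.clip(round(effect.frac_dopaminergic * n_y), 0, n_y))
    start = (n_y - k) // 2
    dopa_ys = set(ys[start:start + k].tolist())
    shell_ys = set(ys[max(0, start - 2):start].tolist()) | set(
        ys[start + k:start + k + 2].tolist()
    )

    class_map = np.zeros(geometry.shape, dtype=np.int16)
    yy = np.indices(geometry.shape)[1]
    class_map[caudate] = GROUND_TRUTH_CLASSES["null"]
    class_map[caudate & np.isin(yy, list(shell_ys))] = GROUND_TRUTH_CLASSES["connected_constant"]
    class_map[caudate & np.isin(yy, list(dopa_ys))] = GROUND_TRUTH_CLASSES["dopaminergic_invertedU"]

    couplings = {
        "a_cells": {
            name: float(coupling_for_correlation(r, effect.confound_weight,
                                                 sigma_e=effect.noise_sd))
            for name, r in zip(CELL_NAMES, effect.r_cells)
        },
        "a_constant": float(coupling_for_correlation(
            effect.r_constant, effect.confound_weight, sigma_e=effect.noise_sd)),
    }
    return GroundTruth(class_map=class_map, effect=effect, rng_seed=int(rng_seed),
                       couplings=couplings)


def simulate_cohort(
    geometry: PhantomGeometry,
    design: CohortDesign,
    effect: EffectSpec,
    n_timepoints: int = 150,
    tr: float = 2.0,
    rng_seed: int = 0,
    band: tuple[float, float] = (0.009, 0.08),
    baseline: float = 1000.0,
    amplitude: float = 10.0,
) -> tuple[list[BoldRun], GroundTruth]:
    """Simulate one BOLD run per subject-session with planted correlations.

    Per run (deterministic child RNG per subject-session) the generator
    draws one seed signal, one shared physiological confound and
    independent per-voxel noise, all band-limited to ``band`` so temporal
    filtering downstream is variance-neutral, then mixes them per region:

    - midbrain seed voxels: seed signal plus 10% independent noise;
    - dopaminergic caudate voxels: seed coupling solved per design cell so
      the population correlation equals ``effect.r_cells`` for that
      subject-session's cell;
    - connected-constant caudate voxels, putamen and ventral striatum:
      constant coupling at ``effect.r_constant``;
    - null caudate voxels: confound plus noise only;
    - white matter and CSF: the shared confound plus 30% noise;
    - other brain: pure noise. Background voxels stay at zero.

    Series are scaled by ``amplitude`` and offset by ``baseline`` (both
    correlation-neutral), stored float32.
    """
    # Solve all couplings up front so an unreachable cell fails fast,
    # naming the offending cell.
    try:
        truth = _assign_ground_truth(geometry, effect, rng_seed)
    except ValueError as err:
        raise ValueError(f"effect specification invalid: {err}") from err
    a_cells = [truth.couplings["a_cells"][name] for name in CELL_NAMES]
    a_const = truth.couplings["a_constant"]
    b = effect.confound_weight
    sigma_e = effect.noise_sd

    brain = geometry.mask("brain")
    brain_idx = np.argwhere(brain)
    region_rows = {
        name: np.flatnonzero(geometry.labels[brain] == code)
        for name, code in REGION_LABELS.items()
        if code > 0
    }
    class_rows = {
        name: np.flatnonzero(truth.class_map[brain] == code)
        for name, code in GROUND_TRUTH_CLASSES.items()
    }

    runs: list[BoldRun] = []
    for subject_id, session, drug in design.iter_runs():
        cell = cell_index(design.span_group(subject_id), drug)
        rng = _child_rng(rng_seed, "run", subject_id, session)
        seed_sig = _band_limited_matrix(1, n_timepoints, tr, band, rng)[0]
        confound = _band_limited_matrix(1, n_timepoints, tr, band, rng)[0]
        noise = _band_limited_matrix(len(brain_idx), n_timepoints, tr, band, rng)

        series = np.empty((len(brain_idx), n_timepoints))
        series[:] = sigma_e * noise  # default: other_brain, pure noise
        rows = region_rows["midbrain_seed"]
        series[rows] = seed_sig + 0.1 * noise[rows]
        for name in ("white_matter", "csf"):
            rows = region_rows[name]
            series[rows] = confound + 0.3 * noise[rows]
        for name in ("putamen", "ventral_striatum"):
            rows = region_rows[name]
            series[rows] = a_const * seed_sig + b * confound + sigma_e * noise[rows]
        rows = class_rows["connected_constant"]
        series[rows] = a_const * seed_sig + b * confound + sigma_e * noise[rows]
        rows = class_rows["dopaminergic_invertedU"]
        series[rows] = a_cells[cell] * seed_sig + b * confound + sigma_e * noise[rows]
        rows = class_rows["null"]
        series[rows] = b * confound + sigma_e * noise[rows]

        data = np.zeros((*geometry.shape, n_timepoints), dtype=np.float32)
        data[tuple(brain_idx.T)] = (baseline + amplitude * series).astype(np.float32)
        runs.append(BoldRun(data=data, tr=tr, affine=geometry.affine.copy(),
                            subject_id=subject_id, session=session, drug=drug))
    return runs, truth
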