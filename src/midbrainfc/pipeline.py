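"""End-to-end driver: simulate -> preprocess -> connectivity -> group stats -> overlap.

:func:`run_pipeline` executes the whole analysis on a synthetic cohort and
returns (and optionally writes) a report bundle containing the group t-map
summary, the recovered inverted-U voxel set, span-connectivity correlations
per drug condition with the Fisher comparison Z, Venn overlap counts
overall and per caudate subdivision with the chi-square proportion test,
and parameter-recovery metrics against the planted ground truth. Runs with
a fixed seed are deterministic.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from .connectivity import ConnectivityMap, seed_connectivity_map
from .group_stats import (
    ContrastSpec,
    ThresholdSpec,
    compare_correlations,
    correlate_with_span,
    interaction_contrast_map,
    one_sample_t_map,
    small_volume_threshold,
    uncorrected_threshold,
)
from .overlap import VoxelSet, chi_square_overlap, overlap_counts, split_caudate
from .preprocess import BoldRun, FilterBand, preprocess_run
from .synthetic import (
    CELL_NAMES,
    CohortDesign,
    EffectSpec,
    GroundTruth,
    PhantomGeometry,
    balanced_cohort_design,
    cell_index,
    make_phantom_geometry,
    simulate_cohort,
)

__all__ = ["RunConfig", "run_pipeline", "connectivity_maps_for_cohort", "write_report"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline settings, prefilled with the study defaults."""

    out_dir: "str | None" = None
    seed: int = 0
    # acquisition / simulation
    n_timepoints: int = 150
    tr: float = 2.0
    n_low: int = 8
    n_high: int = 8
    r_cells: tuple[float, float, float, float] = (0.1, 0.5, 0.5, 0.1)
    frac_dopaminergic: float = 0.25
    r_constant: float = 0.3
    noise_sd: float = 1.0
    confound_weight: float = 0.5
    # preprocessing
    band: tuple[float, float] = (0.009, 0.08)
    fwhm_mm: float = 4.0
    # group statistics
    contrast_weights: tuple[float, float, float, float] = (-0.5, 0.5, 0.5, -0.5)
    q: float = 0.05
    min_cluster: int = 20
    cluster_connectivity: int = 6
    uncorrected_p: float = 0.05
    span_cutoff: float = 3.5
    # overlap
    y_boundary_mm: float = 2.0

    def validate(self) -> None:
        FilterBand(*self.band).validate_for_tr(self.tr)
        ContrastSpec(weights=tuple(self.contrast_weights))
        ThresholdSpec(q=self.q, min_cluster=self.min_cluster,
                      cluster_connectivity=self.cluster_connectivity)
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be non-negative")
        if not 0 < self.uncorrected_p < 1:
            raise ValueError("uncorrected_p must lie in (0, 1)")
        EffectSpec(r_cells=tuple(self.r_cells), frac_dopaminergic=self.frac_dopaminergic,
                   r_constant=self.r_constant, noise_sd=self.noise_sd,
                   confound_weight=self.confound_weight)

    @property
    def effect(self) -> EffectSpec:
        return EffectSpec(r_cells=tuple(self.r_cells),
                          frac_dopaminergic=self.frac_dopaminergic,
                          r_constant=self.r_constant, noise_sd=self.noise_sd,
                          confound_weight=self.confound_weight)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        kwargs = dict(payload)
        for key in ("band", "r_cells", "contrast_weights"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: "str | Path") -> "RunConfig":
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text))  # YAML is a JSON superset


def connectivity_maps_for_cohort(runs: "list[BoldRun]", geometry: PhantomGeometry,
                                 config: RunConfig) -> list[ConnectivityMap]:
    """Preprocess every run and map seed connectivity over the brain mask."""
    seed_mask = geometry.mask("midbrain_seed")
    brain_mask = geometry.mask("brain")
    wm_mask = geometry.mask("white_matter")
    csf_mask = geometry.mask("csf")
    maps = []
    for run in runs:
        pre = preprocess_run(run, band=config.band, fwhm_mm=config.fwhm_mm,
                             wm_mask=wm_mask, csf_mask=csf_mask)
        maps.append(seed_connectivity_map(pre, seed_mask, brain_mask,
                                          seed_name="midbrain"))
    return maps


def run_pipeline(config: RunConfig, write: bool | None = None) -> dict:
    """Run the full synthetic-cohort analysis; returns the report bundle."""
    config.validate()
    if write is None:
        write = config.out_dir is not None

    geometry = make_phantom_geometry()
    design = balanced_cohort_design(n_low=config.n_low, n_high=config.n_high,
                                    rng_seed=config.seed, span_cutoff=config.span_cutoff)
    runs, truth = simulate_cohort(geometry, design, config.effect,
                                  n_timepoints=config.n_timepoints, tr=config.tr,
                                  rng_seed=config.seed, band=config.band)
    logger.info("simulated %d runs on grid %s", len(runs), geometry.shape)
    maps = connectivity_maps_for_cohort(runs, geometry, config)
    results = analyze_cohort(maps, design, geometry, config, truth=truth)

    if write:
        out = Path(config.out_dir or "midbrainfc_out")
        out.mkdir(parents=True, exist_ok=True)
        mio.save_json(config.to_dict(), out / "config.json")
        mio.save_labels(geometry, out / "labels.nii")
        mio.save_ground_truth(truth, out / "ground_truth.json")
        paths = {}
        for run, cmap in zip(runs, maps):
            stem = out / f"{run.subject_id}_{run.session}_{run.drug}"
            mio.save_bold_run(run, stem.with_name(stem.name + "_bold.nii"))
            mio.save_connectivity_map(cmap, geometry.affine, stem)
            paths[(run.subject_id, run.session)] = stem.name + "_bold.nii"
        mio.write_design_tsv(design, out / "design.tsv", paths=paths)
        mio.save_voxel_set(results["_sets"]["interaction_fdr"], geometry.affine,
                           out / "interaction_invertedU")
        mio.save_voxel_set(results["_sets"]["connectivity_caudate"], geometry.affine,
                           out / "connectivity_caudate")
        write_report(results, out)
    return results


def analyze_cohort(maps: "list[ConnectivityMap]", design: CohortDesign,
                   geometry: PhantomGeometry, config: RunConfig,
                   truth: GroundTruth | None = None) -> dict:
    """Group statistics + overlap analysis on precomputed connectivity maps."""
    caudate = geometry.mask("caudate")
    contrast = ContrastSpec(weights=tuple(config.contrast_weights))

    # Overall connectivity: one-sample t across all subject-session maps.
    t_map = one_sample_t_map(maps)
    whole_brain = small_volume_threshold(t_map, ThresholdSpec(
        q=config.q, min_cluster=config.min_cluster,
        cluster_connectivity=config.cluster_connectivity, direction="positive",
        mask_name="brain"))
    # Caudate voxels with significant overall connectivity (FDR, small volume).
    set_connectivity = small_volume_threshold(t_map, ThresholdSpec(
        q=config.q, small_volume_mask=caudate, min_cluster=1,
        cluster_connectivity=config.cluster_connectivity, direction="positive",
        mask_name="caudate"))

    # Drug-by-span interaction (inverted-U contrast).
    inter_map = interaction_contrast_map(maps, design, contrast)
    set_invu_fdr = small_volume_threshold(inter_map, ThresholdSpec(
        q=config.q, small_volume_mask=caudate, min_cluster=config.min_cluster,
        cluster_connectivity=config.cluster_connectivity, direction="positive",
        mask_name="caudate"))
    set_invu_unc = uncorrected_threshold(inter_map, alpha=config.uncorrected_p,
                                         mask=caudate, direction="positive")

    # Span-connectivity correlations over the recovered voxels, per condition.
    span_stats = _span_correlations(maps, design, set_invu_fdr)

    # Venn overlap: significant overall connectivity (A) vs inverted-U (B).
    venn = overlap_counts(set_connectivity, set_invu_unc)
    headbody, tail = split_caudate(caudate, geometry.affine, config.y_boundary_mm)
    regional = {}
    chi = None
    region_counts = {}
    for name, region in (("headbody", headbody), ("tail", tail)):
        a = len(set_connectivity.restricted_to(region))
        inter = len(VoxelSet.from_mask(set_connectivity.to_mask()
                                       & set_invu_unc.to_mask() & region))
        region_counts[name] = (inter, a - inter)
        regional[name] = {"n_connectivity": a, "n_overlap": inter}
    if all(sum(region_counts[n]) >= 1 for n in region_counts) and (
            sum(c[0] for c in region_counts.values()) > 0
            and sum(c[1] for c in region_counts.values()) > 0):
        res = chi_square_overlap(region_counts["headbody"], region_counts["tail"])
        chi = {"chi2": res.chi2, "p": res.p, "df": res.df,
               "higher_region": "headbody" if res.higher_region == 1 else "tail",
               "proportions": res.proportions}

    cell_means = _cell_means_over(maps, design, set_invu_fdr)
    results = {
        "config": config.to_dict(),
        "group_t": {
            "df": t_map.df,
            "n_significant_whole_brain": len(whole_brain),
            "n_significant_caudate": len(set_connectivity),
            "max_t": float(np.max(t_map.stat[t_map.valid])) if t_map.valid.any() else None,
        },
        "interaction": {
            "df": inter_map.df,
            "n_recovered_fdr": len(set_invu_fdr),
            "n_uncorrected": len(set_invu_unc),
            "cell_means": cell_means,
        },
        "span_correlation": span_stats,
        "overlap": {
            "n_only_connectivity": venn.n_only_a,
            "n_only_invertedU": venn.n_only_b,
            "n_intersection": venn.n_intersection,
            "percent_of_connectivity": venn.percent_of_a,
            "regional": regional,
            "chi_square": chi,
        },
        "_sets": {
            "interaction_fdr": set_invu_fdr,
            "interaction_uncorrected": set_invu_unc,
            "connectivity_caudate": set_connectivity,
            "whole_brain": whole_brain,
        },
        "_maps": {"group_t": t_map, "interaction": inter_map},
    }
    if truth is not None:
        results["recovery"] = recovery_metrics(set_invu_fdr, truth)
    return results


def _span_correlations(maps, design, voxel_set: VoxelSet) -> dict:
    if len(voxel_set) == 0:
        return {"placebo": None, "bromocriptine": None, "comparison": None,
                "note": "no recovered voxels"}
    mask = voxel_set.to_mask()
    scores = [design.span_scores[s] for s in design.subject_ids]
    out: dict = {}
    rs = {}
    for drug in ("placebo", "bromocriptine"):
        values = []
        for sid in design.subject_ids:
            cmap = next(m for m in maps if m.subject_id == sid and m.drug == drug)
            values.append(float(cmap.z[mask].mean()))
        try:
            r, p, n = correlate_with_span(values, scores)
        except ValueError:
            out[drug] = None
            continue
        rs[drug] = (r, n)
        out[drug] = {"r": r, "p": p, "n": n}
    if "placebo" in rs and "bromocriptine" in rs:
        z, p = compare_correlations(rs["placebo"][0], rs["placebo"][1],
                                    rs["bromocriptine"][0], rs["bromocriptine"][1])
        out["comparison"] = {"Z": z, "p": p}
    else:
        out["comparison"] = None
    return out


def _cell_means_over(maps, design, voxel_set: VoxelSet) -> "dict | None":
    """Mean z per design cell over the recovered voxels (the inverted-U plot)."""
    if len(voxel_set) == 0:
        return None
    mask = voxel_set.to_mask()
    sums = np.zeros(4)
    counts = np.zeros(4)
    for m in maps:
        c = cell_index(design.span_group(str(m.subject_id)), str(m.drug))
        sums[c] += float(m.z[mask].mean())
        counts[c] += 1
    means = sums / counts
    return dict(zip(CELL_NAMES, means.tolist()))


def recovery_metrics(recovered: VoxelSet, truth: GroundTruth) -> dict:
    """Sensitivity on planted inverted-U voxels; false-positive rate on null voxels."""
    rec = recovered.to_mask()
    dopa = truth.mask("dopaminergic_invertedU")
    null = truth.mask("null")
    sens = float((rec & dopa).sum() / dopa.sum()) if dopa.any() else float("nan")
    fpr = float((rec & null).sum() / null.sum()) if null.any() else float("nan")
    return {"sensitivity": sens, "false_positive_rate": fpr,
            "n_planted": int(dopa.sum()), "n_null": int(null.sum()),
            "n_recovered": len(recovered)}


def write_report(results: dict, out_dir: "str | Path") -> Path:
    """Write the report bundle as JSON plus a human-readable text summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    serializable = {k: v for k, v in results.items() if not k.startswith("_")}
    mio.save_json(serializable, out / "report.json")

    lines = ["midbrain connectivity pipeline report", "=" * 38, ""]
    g = results["group_t"]
    lines.append(f"Group connectivity t-map (df={g['df']}): "
                 f"{g['n_significant_whole_brain']} voxels whole-brain, "
                 f"{g['n_significant_caudate']} caudate voxels significant "
                 f"(FDR, small volume).")
    it = results["interaction"]
    lines.append(f"Inverted-U interaction (df={it['df']}): "
                 f"{it['n_recovered_fdr']} caudate voxels (FDR, small volume, "
                 f"cluster-filtered); {it['n_uncorrected']} at the uncorrected threshold.")
    if it["cell_means"]:
        cells = ", ".join(f"{k}={v:.3f}" for k, v in it["cell_means"].items())
        lines.append(f"Cell means over recovered voxels: {cells}")
    sc = results["span_correlation"]
    for drug in ("placebo", "bromocriptine"):
        st = sc.get(drug)
        if st:
            lines.append(f"Span-connectivity correlation ({drug}): "
                         f"r={st['r']:.3f}, p={st['p']:.4g}, n={st['n']}")
    if sc.get("comparison"):
        lines.append(f"Correlation comparison (placebo vs drug): "
                     f"Z={sc['comparison']['Z']:.3f}, p={sc['comparison']['p']:.4g}")
    ov = results["overlap"]
    denom = ov["n_intersection"] + ov["n_only_connectivity"]
    lines.append(f"Venn overlap: {ov['n_intersection']}/{denom} connectivity voxels "
                 f"also inverted-U ({ov['percent_of_connectivity']}%); "
                 f"{ov['n_only_invertedU']} inverted-U only.")
    if ov["chi_square"]:
        c = ov["chi_square"]
        lines.append(f"Head/body vs tail overlap proportions: chi2(df={c['df']}) = "
                     f"{c['chi2']:.2f}, p={c['p']:.3g}; higher in {c['higher_region']}.")
    if "recovery" in results:
        r = results["recovery"]
        lines.append(f"Ground-truth recovery: sensitivity={r['sensitivity']:.3f}, "
                     f"false-positive rate={r['false_positive_rate']:.3f} "
                     f"({r['n_recovered']} recovered / {r['n_planted']} planted).")
    path = out / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    return path
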