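"""Study-level validation routines on the synthetic phantom.

These run the generator and pipeline end to end under controlled effect
specifications and summarize how well the analysis recovers what was
planted: the Fisher-z level of a known planted correlation, the type-I
behavior of the inverted-U interaction under a null effect, and
sensitivity / false-positive rate for planted dopaminergic voxels.
"""

from __future__ import annotations

import numpy as np

from .connectivity import seed_connectivity_map
from .pipeline import RunConfig, run_pipeline
from .synthetic import (
    CohortDesign,
    EffectSpec,
    balanced_cohort_design,
    make_phantom_geometry,
    simulate_cohort,
)
from .group_stats import ContrastSpec, interaction_contrast_map
from .pipeline import connectivity_maps_for_cohort

__all__ = [
    "planted_z_recovery",
    "type1_calibration",
    "recovery_study",
]


def _single_subject_design(span_score: float = 4.0) -> CohortDesign:
    return CohortDesign(
        subject_ids=("sub-01",),
        span_scores={"sub-01": span_score},
        drug_by_session={"sub-01": {"ses-1": "placebo", "ses-2": "bromocriptine"}},
    )


def planted_z_recovery(planted_r: float = 0.6, n_runs: int = 200,
                       n_timepoints: int = 150, tr: float = 2.0,
                       rng_seed: int = 0) -> dict:
    """Mean Fisher z at voxels with a planted correlation, across seeded runs.

    Simulates independent runs (one two-session subject per replicate, so
    ``n_runs`` runs use ``n_runs // 2`` replicates), maps seed connectivity
    on the raw generated series restricted to the caudate, and averages z
    over the planted voxels and runs. Under the generative model the
    population value is atanh(planted_r).
    """
    geometry = make_phantom_geometry()
    effect = EffectSpec.null(r=planted_r)
    design = _single_subject_design()
    seed_mask = geometry.mask("midbrain_seed")
    caudate = geometry.mask("caudate")
    z_means = []
    n_reps = max(1, n_runs // 2)
    truth = None
    for rep in range(n_reps):
        runs, truth = simulate_cohort(geometry, design, effect,
                                      n_timepoints=n_timepoints, tr=tr,
                                      rng_seed=rng_seed * 1_000_003 % (2 ** 31) + rep)
        dopa = truth.mask("dopaminergic_invertedU")
        for run in runs:
            cmap = seed_connectivity_map(run, seed_mask, caudate | seed_mask)
            z_means.append(float(cmap.z[dopa & cmap.valid].mean()))
    return {
        "mean_z": float(np.mean(z_means)),
        "expected_z": float(np.arctanh(planted_r)),
        "n_runs": len(z_means),
        "n_voxels_per_run": int(truth.mask("dopaminergic_invertedU").sum()),
    }


def type1_calibration(n_replicates: int = 20, alpha: float = 0.05,
                      rng_seed: int = 0, config: RunConfig | None = None) -> dict:
    """Interaction-contrast calibration under a null effect (all cells equal).

    For each seeded replicate the full pipeline (simulate, preprocess,
    connectivity, interaction contrast) runs with every design cell planted
    at the same correlation, so no voxel carries a true interaction.
    Reports the uncorrected rejection rate at ``alpha`` pooled over gray
    voxels of every replicate, and how many replicates leave the
    FDR/small-volume/cluster-thresholded inverted-U set empty.
    """
    base = config or RunConfig()
    geometry = make_phantom_geometry()
    gray = geometry.mask("brain") & ~geometry.mask("midbrain_seed") \
        & ~geometry.mask("white_matter") & ~geometry.mask("csf")
    n_rejections = 0
    n_voxels = 0
    n_empty = 0
    for rep in range(n_replicates):
        seed = (rng_seed * 1_000_003 + 7919 * rep) % (2 ** 31)
        cfg = RunConfig(**{**base.to_dict(), "seed": seed,
                           "r_cells": (base.r_constant,) * 4, "out_dir": None})
        res = run_pipeline(cfg, write=False)
        inter = res["_maps"]["interaction"]
        valid = inter.valid & gray
        n_rejections += int((inter.p[valid] < alpha).sum())
        n_voxels += int(valid.sum())
        if len(res["_sets"]["interaction_fdr"]) == 0:
            n_empty += 1
    return {
        "rejection_rate": n_rejections / n_voxels,
        "alpha": alpha,
        "n_voxels": n_voxels,
        "n_replicates": n_replicates,
        "n_empty_fdr_sets": n_empty,
    }


def recovery_study(n_seeds: int = 20, rng_seed: int = 0,
                   config: RunConfig | None = None) -> dict:
    """Sensitivity and false-positive rate for the planted inverted-U voxels.

    Runs the full pipeline once per seed with the default inverted-U effect
    (r_cells 0.1/0.5/0.5/0.1, 8 low + 8 high subjects) and averages: the
    fraction of planted dopaminergic voxels recovered by the
    FDR/small-volume/cluster threshold, the fraction of null caudate voxels
    falsely recovered, and the drug-minus-placebo cell-mean differences per
    span group over the recovered voxels (the inverted-U signature: drug
    raises connectivity in low-span, lowers it in high-span).
    """
    base = config or RunConfig()
    sens, fpr, d_low, d_high = [], [], [], []
    for rep in range(n_seeds):
        seed = (rng_seed * 1_000_003 + 104729 * rep) % (2 ** 31)
        cfg = RunConfig(**{**base.to_dict(), "seed": seed, "out_dir": None})
        res = run_pipeline(cfg, write=False)
        sens.append(res["recovery"]["sensitivity"])
        fpr.append(res["recovery"]["false_positive_rate"])
        cells = res["interaction"]["cell_means"]
        if cells is not None:
            d_low.append(cells["low-bromocriptine"] - cells["low-placebo"])
            d_high.append(cells["high-bromocriptine"] - cells["high-placebo"])
    return {
        "sensitivity": float(np.mean(sens)),
        "false_positive_rate": float(np.mean(fpr)),
        "n_seeds": n_seeds,
        "mean_drug_effect_low_span": float(np.mean(d_low)) if d_low else None,
        "mean_drug_effect_high_span": float(np.mean(d_high)) if d_high else None,
    }
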