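"""NIfTI / TSV / JSON reading and writing for every pipeline artifact."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMap
from .overlap import VoxelSet
from .preprocess import BoldRun
from .synthetic import CohortDesign, GroundTruth, PhantomGeometry, REGION_LABELS

__all__ = [
    "save_bold_run", "load_bold_run",
    "save_labels", "load_labels",
    "save_mask", "load_mask",
    "save_connectivity_map", "load_connectivity_map",
    "save_voxel_set", "load_voxel_set",
    "write_design_tsv", "read_subject_table",
    "save_ground_truth", "load_ground_truth",
    "save_json", "load_json",
]

DRUG_LABELS = ("placebo", "bromocriptine")


def save_bold_run(run: BoldRun, path: "str | Path") -> Path:
    """Write a run as NIfTI-1 4D float32 with TR recorded in the header."""
    img = nib.Nifti1Image(np.asarray(run.data, dtype=np.float32), run.affine)
    zooms = (*np.linalg.norm(run.affine[:3, :3], axis=0), run.tr)
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    path = Path(path)
    nib.save(img, path)
    return path


def load_bold_run(path: "str | Path", subject_id: str | None = None,
                  session: str | None = None, drug: str | None = None,
                  tr: float | None = None) -> BoldRun:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if tr is None:
        tr = float(img.header.get_zooms()[3])
    return BoldRun(data=data, tr=tr, affine=np.asarray(img.affine),
                   subject_id=subject_id, session=session, drug=drug)


def save_labels(geometry: PhantomGeometry, path: "str | Path") -> Path:
    img = nib.Nifti1Image(geometry.labels.astype(np.int16), geometry.affine)
    path = Path(path)
    nib.save(img, path)
    return path


def load_labels(path: "str | Path", y_boundary_mm: float = 2.0) -> PhantomGeometry:
    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj).astype(np.int16)
    affine = np.asarray(img.affine)
    voxel_size = tuple(np.linalg.norm(affine[:3, :3], axis=0))
    return PhantomGeometry(shape=labels.shape, voxel_size=voxel_size,
                           affine=affine, labels=labels, y_boundary_mm=y_boundary_mm)


def save_mask(mask: np.ndarray, affine: np.ndarray, path: "str | Path") -> Path:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    path = Path(path)
    nib.save(img, path)
    return path


def load_mask(path: "str | Path") -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj).astype(bool)


def save_connectivity_map(cmap: ConnectivityMap, affine: np.ndarray,
                          stem: "str | Path") -> tuple[Path, Path]:
    """Write the z map and validity mask as a NIfTI pair ``<stem>_z/_valid``."""
    stem = Path(stem)
    z_path = stem.with_name(stem.name + "_z.nii")
    v_path = stem.with_name(stem.name + "_valid.nii")
    nib.save(nib.Nifti1Image(cmap.z.astype(np.float32), affine), z_path)
    nib.save(nib.Nifti1Image(cmap.valid.astype(np.uint8), affine), v_path)
    return z_path, v_path


def load_connectivity_map(z_path: "str | Path", valid_path: "str | Path",
                          **labels) -> ConnectivityMap:
    z = np.asanyarray(nib.load(str(z_path)).dataobj).astype(float)
    valid = np.asanyarray(nib.load(str(valid_path)).dataobj).astype(bool)
    return ConnectivityMap(z=z, valid=valid, **labels)


def save_voxel_set(vs: VoxelSet, affine: np.ndarray, stem: "str | Path") -> tuple[Path, Path]:
    """Write a voxel set as a binary NIfTI mask plus a TSV of voxel indices."""
    stem = Path(stem)
    mask_path = stem.with_name(stem.name + "_mask.nii")
    tsv_path = stem.with_name(stem.name + "_voxels.tsv")
    save_mask(vs.to_mask(), affine, mask_path)
    df = pd.DataFrame(vs.voxels, columns=["i", "j", "k"])
    df.to_csv(tsv_path, sep="\t", index=False)
    with open(stem.with_name(stem.name + "_provenance.json"), "w") as fh:
        json.dump(_jsonable(dict(vs.provenance)), fh, indent=2, sort_keys=True)
    return mask_path, tsv_path


def load_voxel_set(tsv_path: "str | Path", shape: tuple[int, int, int]) -> VoxelSet:
    df = pd.read_csv(tsv_path, sep="\t")
    return VoxelSet(voxels=df[["i", "j", "k"]].to_numpy(), shape=shape)


def write_design_tsv(design: CohortDesign, path: "str | Path",
                     paths: "dict[tuple[str, str], str] | None" = None) -> Path:
    rows = []
    for sid, session, drug in design.iter_runs():
        rows.append({
            "subject_id": sid,
            "session": session,
            "drug": drug,
            "span_score": design.span_scores[sid],
            "span_group": design.span_group(sid),
            "path": (paths or {}).get((sid, session), ""),
        })
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_subject_table(path: "str | Path", span_cutoff: float = 3.5) -> CohortDesign:
    """Load and schema-validate a subject table into a CohortDesign.

    Requires columns subject_id, session, drug, span_score; errors name the
    offending row or subject (missing column, duplicate subject-session,
    unknown drug label, inconsistent span score).
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "session": str, "drug": str})
    required = ["subject_id", "session", "drug", "span_score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"subject table is missing column(s): {missing}")
    dup = df.duplicated(subset=["subject_id", "session"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(f"duplicate subject-session row: {row['subject_id']}/{row['session']}")
    bad = ~df["drug"].isin(DRUG_LABELS)
    if bad.any():
        row = df[bad].iloc[0]
        raise ValueError(f"unknown drug label {row['drug']!r} in row for "
                         f"{row['subject_id']}/{row['session']}")
    scores: dict[str, float] = {}
    sessions: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        sid = row["subject_id"]
        score = float(row["span_score"])
        if sid in scores and scores[sid] != score:
            raise ValueError(f"subject {sid} has inconsistent span scores")
        scores[sid] = score
        sessions.setdefault(sid, {})[row["session"]] = row["drug"]
    subject_ids = tuple(dict.fromkeys(df["subject_id"]))
    return CohortDesign(subject_ids=subject_ids, span_scores=scores,
                        drug_by_session=sessions, span_cutoff=span_cutoff)


def save_ground_truth(truth: GroundTruth, path: "str | Path") -> Path:
    path = Path(path)
    path.write_text(truth.to_json())
    return path


def load_ground_truth(path: "str | Path") -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def save_json(obj, path: "str | Path") -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")
    return path


def load_json(path: "str | Path"):
    return json.loads(Path(path).read_text())
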