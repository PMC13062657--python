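"""File formats and provenance: NIfTI volumes, CSV tables, configs.

Conventions, stated once and enforced here: voxel indices are 0-based and
half-open internally; coordinates are reported in millimetres with MNI-style
signs (x lateral+, y rostral+, z dorsal+); masks are stored as unsigned
8-bit, probabilities as 32-bit float; affines round-trip unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import SubjectConnectivity
from .regions import ALL_REGIONS

REQUIRED_COVARIATE_COLUMNS = ("subject_id", "study_id", "group")


def write_volume(data: np.ndarray, affine: np.ndarray, path, dtype=None) -> Path:
    """Write one volume as NIfTI-1 (masks uint8, probabilities float32)."""
    path = Path(path)
    if dtype is None:
        dtype = np.uint8 if data.dtype == bool else np.float32
    img = nib.Nifti1Image(np.asarray(data).astype(dtype), np.asarray(affine))
    nib.save(img, path)
    return path


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine.copy()


def read_mask(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a binary mask, rejecting volumes with values outside {0, 1}."""
    data, affine = read_volume(path)
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{path}: mask has non-binary values {vals[:10]}")
    return data.astype(bool), affine


def check_affines_match(affine_a, affine_b, name_a="volume A", name_b="volume B"):
    if not np.allclose(affine_a, affine_b, atol=1e-5):
        raise ValueError(f"affine mismatch between {name_a} and {name_b}")


def write_covariates(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: covariate table missing columns {missing}")
    if df["study_id"].isna().any():
        raise ValueError(f"{path}: covariate table has missing study_id values")
    return df


def read_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration for output provenance."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_subject(subject: SubjectConnectivity, out_dir) -> Path:
    """Write one subject: 4-D counts, FA/RD, masks, and a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = subject.affine
    write_volume(subject.counts, aff, out_dir / "counts.nii", dtype=np.uint16)
    write_volume(subject.fa, aff, out_dir / "fa.nii")
    write_volume(subject.rd, aff, out_dir / "rd.nii")
    for name in ("striatal_mask", "caudate_mask", "putamen_mask"):
        write_volume(getattr(subject, name), aff, out_dir / f"{name}.nii")
    meta = {
        "subject_id": subject.subject_id,
        "study_id": subject.study_id,
        "group": subject.group,
        "severity_category": subject.severity_category,
        "hemisphere": subject.hemisphere,
        "head_size_scalar": subject.head_size_scalar,
        "streamlines_per_voxel": subject.streamlines_per_voxel,
        "region_names": list(subject.region_names),
        "voxel_mm": list(subject.voxel_mm),
    }
    (out_dir / "subject.json").write_text(json.dumps(meta, indent=2))
    return out_dir


def read_subject(subject_dir) -> SubjectConnectivity:
    """Read a subject directory written by :func:`write_subject`."""
    d = Path(subject_dir)
    meta = json.loads((d / "subject.json").read_text())
    counts, aff = read_volume(d / "counts.nii")
    fa, aff_fa = read_volume(d / "fa.nii")
    check_affines_match(aff, aff_fa, d / "counts.nii", d / "fa.nii")
    rd, aff_rd = read_volume(d / "rd.nii")
    check_affines_match(aff, aff_rd, d / "counts.nii", d / "rd.nii")
    masks = {}
    for name in ("striatal_mask", "caudate_mask", "putamen_mask"):
        masks[name], aff_m = read_mask(d / f"{name}.nii")
        check_affines_match(aff, aff_m, d / "counts.nii", d / f"{name}.nii")
    if list(meta["region_names"]) != list(ALL_REGIONS):
        raise ValueError(f"{d}: unexpected bait-region ordering")
    frac = np.full(fa.shape, np.nan, dtype=np.float32)  # truth not serialized
    return SubjectConnectivity(
        counts=counts.astype(np.uint16),
        region_names=ALL_REGIONS,
        streamlines_per_voxel=int(meta["streamlines_per_voxel"]),
        fa=fa.astype(np.float32),
        rd=rd.astype(np.float32),
        striatal_mask=masks["striatal_mask"],
        caudate_mask=masks["caudate_mask"],
        putamen_mask=masks["putamen_mask"],
        true_striosome_fraction=frac,
        true_bias=frac,
        striatal_content=frac,
        head_size_scalar=float(meta["head_size_scalar"]),
        subject_id=meta["subject_id"],
        study_id=meta["study_id"],
        group=meta["group"],
        severity_category=meta.get("severity_category"),
        hemisphere=meta["hemisphere"],
        voxel_mm=tuple(meta["voxel_mm"]),
    )


def dump_manifest(manifest: dict, path) -> Path:
    path = Path(path)

    def default(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"cannot serialize {type(obj)}")

    path.write_text(json.dumps(manifest, indent=2, default=default))
    return path
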