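"""File exchange: ratings CSV, beta maps NIfTI, truth/results JSON, config YAML."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .synthetic import RATING_COLUMNS, BetaMapSet, SyntheticTruth

__all__ = [
    "write_ratings_csv",
    "read_ratings_csv",
    "write_beta_maps",
    "read_beta_maps",
    "write_truth_json",
    "read_truth_json",
    "write_json",
    "read_json",
    "write_yaml",
    "read_yaml",
]


def write_ratings_csv(dataset: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    dataset.to_csv(path, index=False)
    return path


def read_ratings_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ratings CSV is missing required columns: {missing}")
    bad = df[(df["intensity_rating"] < 0) | (df["intensity_rating"] > 10)]
    if not bad.empty:
        raise ValueError("intensity ratings outside the 0-10 VAS range")
    return df


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    return np.diag([*voxel_size, 1.0])


def write_beta_maps(maps: BetaMapSet, prefix: str | Path) -> tuple[Path, Path, Path]:
    """Write a map set as 4-D NIfTI (subjects on axis 3) + mask + subject list."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    vol4d = np.zeros((*maps.shape, maps.n_subjects), dtype=np.float32)
    for i in range(maps.n_subjects):
        vol4d[..., i][maps.mask] = maps.data[i]
    affine = _affine(maps.voxel_size)
    data_path = prefix.with_suffix(".nii.gz")
    mask_path = Path(f"{prefix}_mask.nii.gz")
    subj_path = Path(f"{prefix}_subjects.json")
    nib.save(nib.Nifti1Image(vol4d, affine), str(data_path))
    nib.save(nib.Nifti1Image(maps.mask.astype(np.uint8), affine), str(mask_path))
    subj_path.write_text(
        json.dumps({"subject_ids": maps.subject_ids, "condition": maps.condition})
    )
    return data_path, mask_path, subj_path


def read_beta_maps(prefix: str | Path) -> BetaMapSet:
    prefix = Path(prefix)
    data_path = prefix.with_suffix(".nii.gz")
    mask_path = Path(f"{prefix}_mask.nii.gz")
    subj_path = Path(f"{prefix}_subjects.json")
    try:
        img = nib.load(str(data_path))
        vol4d = np.asarray(img.dataobj, dtype=float)
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    except Exception as exc:  # truncated / malformed files
        raise IOError(f"could not read beta maps at {prefix}: {exc}") from exc
    meta = json.loads(subj_path.read_text())
    voxel_size = tuple(float(v) for v in img.header.get_zooms()[:3])
    data = np.stack([vol4d[..., i][mask] for i in range(vol4d.shape[-1])])
    return BetaMapSet(
        data=data,
        mask=mask,
        subject_ids=list(meta["subject_ids"]),
        condition=meta.get("condition", ""),
        voxel_size=voxel_size,
    )


def write_truth_json(truth: SyntheticTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_jsonable(), indent=1))
    return path


def read_truth_json(path: str | Path) -> SyntheticTruth:
    return SyntheticTruth.from_jsonable(json.loads(Path(path).read_text()))


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


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True))
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_yaml(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(_jsonable(obj), sort_keys=True))
    return path


def read_yaml(path: str | Path):
    return yaml.safe_load(Path(path).read_text())
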