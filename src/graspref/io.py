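"""File formats: NIfTI volumes with JSON sidecars, TSV tables, YAML config."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .synthetic import PatternDataset

__all__ = [
    "VolumeMismatchError",
    "write_volume",
    "read_volume",
    "load_subject_maps",
    "write_pattern_dataset",
    "read_pattern_dataset",
    "write_table",
    "load_config",
    "dump_config",
    "config_hash",
]


class VolumeMismatchError(ValueError):
    """Raised when volumes expected to share a grid/affine do not."""


def _sidecar(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume(path, data: np.ndarray, affine: np.ndarray,
                 metadata: Optional[dict] = None) -> Path:
    """Write a NIfTI-1 volume, with an optional JSON sidecar for metadata."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.asarray(affine, dtype=float))
    nib.save(img, str(path))
    if metadata is not None:
        _sidecar(path).write_text(json.dumps(metadata, indent=2, sort_keys=True))
    return path


def read_volume(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a NIfTI-1 volume; returns (data, affine, sidecar metadata)."""
    path = Path(path)
    img = nib.load(str(path))
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return np.asarray(img.get_fdata()), np.asarray(img.affine), meta


def load_subject_maps(paths: Sequence) -> tuple[np.ndarray, np.ndarray, list]:
    """Load and stack subject maps, enforcing a common grid and affine.

    Returns (data stacked on a leading axis, affine, list of sidecars).
    A mismatched affine or shape raises VolumeMismatchError naming both
    files.
    """
    if not paths:
        raise ValueError("no map paths given")
    data, metas = [], []
    affine0, shape0, first = None, None, None
    for p in paths:
        d, a, meta = read_volume(p)
        if affine0 is None:
            affine0, shape0, first = a, d.shape, p
        else:
            if d.shape != shape0 or not np.allclose(a, affine0):
                raise VolumeMismatchError(
                    f"volume {p} does not match grid/affine of {first}"
                )
        data.append(d)
        metas.append(meta)
    return np.stack(data), affine0, metas


def write_pattern_dataset(path, dataset: PatternDataset) -> Path:
    """Serialize a PatternDataset as long-format TSV + JSON sidecar."""
    path = Path(path)
    R, C, V = dataset.values.shape
    df = pd.DataFrame(
        {
            "run": np.repeat(np.arange(R), C * V),
            "configuration": np.tile(np.repeat(list(dataset.config_labels), V), R),
            "voxel": np.tile(np.arange(V), R * C),
            "value": dataset.values.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)
    meta = {
        "modality": dataset.modality,
        "run_ids": list(map(str, dataset.run_ids)),
        "config_labels": list(dataset.config_labels),
        "n_voxels": V,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_pattern_dataset(path) -> PatternDataset:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(".json").read_text())
    labels = meta["config_labels"]
    R = df.run.nunique()
    V = meta["n_voxels"]
    vals = np.empty((R, len(labels), V))
    for r in range(R):
        sub = df[df.run == r]
        for c, lbl in enumerate(labels):
            vals[r, c] = sub[sub.configuration == lbl].sort_values("voxel").value.to_numpy()
    return PatternDataset(values=vals, modality=meta["modality"],
                          run_ids=meta["run_ids"], config_labels=tuple(labels))


def write_table(path, df: pd.DataFrame) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def dump_config(cfg: dict, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return path


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping, recorded in output sidecars."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
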