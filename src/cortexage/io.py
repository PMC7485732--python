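"""NIfTI / CSV / JSON input-output and artifact hashing."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "save_nifti",
    "load_nifti",
    "write_covariates",
    "read_covariates",
    "write_sidecar",
    "file_sha256",
    "config_hash",
]


def save_nifti(
    data: np.ndarray,
    affine: np.ndarray,
    path: str | Path,
    dtype=np.float32,
) -> Path:
    """Write a volume (or echo-first 4D stack) as NIfTI-1, RAS+.

    4D stacks arrive echo-first ``(e, x, y, z)`` and are stored in NIfTI's
    time-last convention ``(x, y, z, e)``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(data)
    if arr.ndim == 4:
        arr = np.moveaxis(arr, 0, -1)
    img = nib.Nifti1Image(arr.astype(dtype), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; 4D data comes back echo-first ``(e, x, y, z)``."""
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    if arr.ndim == 4:
        arr = np.moveaxis(arr, -1, 0)
    return arr, img.affine


def write_covariates(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["subject_id", "age_years", "sex", "tiv_ml"]
    df[cols].to_csv(path, index=False)
    return path


def read_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_sidecar(payload: dict, path: str | Path) -> Path:
    """JSON sidecar with sorted keys (stable bytes for hashing)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonify))
    return path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(payload: dict) -> str:
    """Stable short hash of a configuration dictionary."""
    blob = json.dumps(payload, sort_keys=True, default=_jsonify).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
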