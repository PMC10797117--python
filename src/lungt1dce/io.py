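"""NIfTI-1 + JSON-sidecar input/output.

Every image written by the pipeline is a NIfTI-1 file whose affine carries
voxel spacing and origin, accompanied by a ``<stem>.json`` sidecar with the
acquisition metadata (TE, TI list, frame interval, seed, ...) that NIfTI
headers cannot hold.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import ImageGrid


def write_nifti(path, data: np.ndarray, grid: ImageGrid, sidecar: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    for a in range(min(grid.ndim, 3)):
        affine[a, a] = grid.spacing[a]
        affine[a, 3] = grid.origin[a]
    img = nib.Nifti1Image(np.asarray(data), affine)
    zooms = list(grid.spacing) + [1.0] * (data.ndim - grid.ndim)
    img.header.set_zooms(tuple(zooms[: data.ndim]))
    nib.save(img, path)
    if sidecar is not None:
        write_sidecar(path, sidecar)
    return path


def sidecar_path(nifti_path) -> Path:
    p = Path(nifti_path)
    stem = p.name
    for suf in (".nii.gz", ".nii"):
        if stem.endswith(suf):
            stem = stem[: -len(suf)]
            break
    return p.with_name(stem + ".json")


def write_sidecar(nifti_path, meta: dict) -> Path:
    sp = sidecar_path(nifti_path)
    sp.write_text(json.dumps(_jsonable(meta), indent=2, sort_keys=True) + "\n")
    return sp


def read_nifti(path) -> tuple[np.ndarray, ImageGrid, dict]:
    """Load image data, grid geometry, and sidecar metadata (``{}`` if absent)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    ndim = min(data.ndim, 3)
    aff = img.affine
    spacing = tuple(float(np.linalg.norm(aff[:3, a])) for a in range(ndim))
    origin = tuple(float(aff[a, 3]) for a in range(ndim))
    grid = ImageGrid(shape=data.shape[:ndim], spacing=spacing, origin=origin)
    sp = sidecar_path(path)
    meta = json.loads(sp.read_text()) if sp.exists() else {}
    return data, grid, meta


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
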