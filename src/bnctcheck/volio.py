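"""Regular-grid volume serialization (NIfTI) and run manifests.

Volumes (phantom labels, densities, flux tallies, dose grids, gamma maps)
are written as NIfTI-1 with the voxel spacing in the affine; a JSON
manifest records the configuration, seed and package version of every
run so reruns are reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .materials import MATERIAL_ORDER, TISSUES
from .phantoms import VoxelPhantom


def _affine(voxel_size, origin) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(
    path: str | Path, data: np.ndarray, voxel_size=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0)
) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64),
                          _affine(voxel_size, origin))
    nib.save(img, path)
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Return (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def write_phantom(phantom: VoxelPhantom, directory: str | Path) -> dict:
    """Phantom as label/density/boron volumes plus a material sidecar table."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, arr in (
        ("material", phantom.material_index.astype(np.float64)),
        ("density", phantom.density),
        ("boron", phantom.boron_conc),
    ):
        files[name] = str(
            write_volume(d / f"{name}.nii.gz", arr, phantom.voxel_size,
                         phantom.origin)
        )
    sidecar = {
        str(i): {
            "name": n,
            "mass_density": TISSUES[n].mass_density,
            "weight_fractions": dict(TISSUES[n].weight_fractions),
        }
        for i, n in enumerate(MATERIAL_ORDER)
    }
    sidecar_path = d / "materials.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    files["materials"] = str(sidecar_path)
    return files


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(path: str | Path, config: dict, seed: int) -> Path:
    path = Path(path)
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
    }
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return path
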