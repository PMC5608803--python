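"""NIfTI, CSV and provenance I/O helpers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__

__all__ = ["load_volume", "save_volume", "write_provenance", "config_hash"]


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI-1 volume; returns (data array, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_volume(data: np.ndarray, path: str | Path, affine=None,
                dtype=np.float32) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=dtype),
                             np.eye(4) if affine is None else affine), str(path))
    return path


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(config, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path: str | Path, config: dict, seed=None) -> Path:
    """Machine-readable record of what produced an output directory."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({
        "version": __version__,
        "config": config,
        "config_hash": config_hash(config),
        "seed": seed,
    }, indent=2, default=float))
    return path
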