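"""NIfTI ingestion and run manifests."""

from __future__ import annotations

import hashlib
import json
import platform
import warnings
from pathlib import Path

import numpy as np

__all__ = ["read_bold_nifti", "read_label_nifti", "write_manifest"]


def read_bold_nifti(path: str | Path, tr_override: float | None = None):
    """Read a 4D BOLD NIfTI; returns (data, tr_seconds).

    The TR is taken from the time-axis header field unless overridden;
    a header/override mismatch is warned about, and a missing or
    implausible header TR (<= 0 or > 30 s) without an override is
    rejected.  Voxel indices are 0-based throughout the package.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 4-D BOLD, got shape {data.shape}")
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr_override is not None:
        if header_tr > 0 and abs(header_tr - tr_override) > 1e-6:
            warnings.warn(
                f"TR override {tr_override}s differs from header {header_tr}s",
                RuntimeWarning, stacklevel=2)
        return data, float(tr_override)
    if not (0 < header_tr <= 30):
        raise ValueError(
            f"{path}: implausible header TR {header_tr}s; pass tr_override")
    return data, header_tr


def read_label_nifti(path: str | Path) -> np.ndarray:
    """Read a 3D integer label volume (tissue or ROI)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D labels, got {data.shape}")
    return np.rint(data).astype(np.int32)


def write_manifest(directory: str | Path, config_dict: dict,
                   stages: dict | None = None) -> Path:
    """Write a machine-readable run manifest (config hash, seeds,
    versions, per-stage wall time) sufficient to reproduce the run."""
    import nibabel
    import pandas
    import scipy

    from . import __version__

    directory = Path(directory)
    payload = json.dumps(config_dict, sort_keys=True, default=str)
    manifest = {
        "config": config_dict,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "versions": {
            "modespec": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "nibabel": nibabel.__version__,
        },
        "stages": stages or {},
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
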