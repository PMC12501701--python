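"""NIfTI and table I/O shared by the CLI and the phantom pipeline."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np


def write_image(path: str | Path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    """Write an array as a NIfTI-1 volume (2D slices become single-slice 3D)."""
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[:, :, np.newaxis]
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(data.astype(np.float64), affine), str(path))


def read_image(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI-1 volume; returns (data, affine), squeezing a trailing
    singleton slice axis back to 2D."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    return data, img.affine


def write_mask(path: str | Path, mask: np.ndarray, affine: np.ndarray | None = None) -> None:
    """Write a boolean mask as a 0/1-coded NIfTI volume."""
    write_image(path, np.asarray(mask).astype(np.uint8), affine)


def write_provenance(path: str | Path, record: dict) -> None:
    """Write a JSON provenance record (config echo, seed, package version)."""
    from . import __version__

    record = dict(record)
    record.setdefault("package_version", __version__)
    Path(path).write_text(json.dumps(record, indent=2, default=str))
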