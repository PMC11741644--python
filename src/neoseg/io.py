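"""Volume I/O (NIfTI / Analyze via nibabel) and run manifests."""

from __future__ import annotations

import json
import os
from typing import Optional, Sequence, Tuple

import nibabel as nib
import numpy as np

from .metrics import LabelVolume

__all__ = [
    "FormatError",
    "LabelValidationError",
    "read_volume",
    "read_label_volume",
    "write_volume",
    "write_label_volume",
    "write_manifest",
]

_SUPPORTED = (".nii", ".nii.gz", ".hdr", ".img")


class FormatError(ValueError):
    """Raised for unsupported or unreadable volume formats."""


class LabelValidationError(ValueError):
    """Raised when a label file contains non-integer values."""


def _check_path(path: str) -> None:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    name = path.lower()
    if not any(name.endswith(ext) for ext in _SUPPORTED):
        raise FormatError(
            f"unsupported volume format for {path!r}; expected one of {_SUPPORTED}"
        )


def read_volume(path) -> Tuple[np.ndarray, Tuple[float, ...]]:
    """Load a volume; returns the data array and per-axis spacing in mm.

    Spacing missing from the header defaults to 1.0 mm isotropic.
    """
    path = str(path)
    _check_path(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[: data.ndim]
    spacing = tuple(float(z) if z and z > 0 else 1.0 for z in zooms)
    return data, spacing


def read_label_volume(path) -> LabelVolume:
    """Load an integer tissue-label map, validating integrality."""
    data, spacing = read_volume(path)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        bad = np.abs(data - rounded) > 1e-6
        if bad.any():
            offenders = np.unique(data[bad])[:5]
            raise LabelValidationError(
                f"label file {path!r} contains non-integer values, e.g. {offenders}"
            )
        data = rounded.astype(np.int64)
    return LabelVolume(data.astype(np.int64), spacing=spacing)


def write_volume(path, data: np.ndarray, spacing: Optional[Sequence[float]] = None) -> None:
    """Write an array as NIfTI/Analyze with the spacing in the header."""
    path = str(path)
    data = np.asarray(data)
    affine = np.eye(4)
    if spacing is not None:
        for i, s in enumerate(spacing[:3]):
            affine[i, i] = float(s)
    img = nib.Nifti1Image(data, affine)
    if spacing is not None:
        img.header.set_zooms(tuple(float(s) for s in spacing[: data.ndim]))
    nib.save(img, path)


def write_label_volume(path, volume: LabelVolume) -> None:
    write_volume(path, volume.labels.astype(np.int16), volume.spacing)


def write_manifest(path, config: dict) -> None:
    """Persist the fully resolved run configuration for exact reproduction."""
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
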