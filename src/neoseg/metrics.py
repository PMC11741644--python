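"""Segmentation quality criteria: per-class Dice overlap and average surface
distance (ASD).

Dice for a tissue label compares the binary masks S (prediction) and T
(truth): ``2|S∩T| / (|S|+|T|)``; 1 means perfect overlap.

ASD extracts the boundary voxels of each mask (face connectivity; the grid
edge counts as outside), then averages, symmetrically over both directions,
the Euclidean distance from each boundary voxel of one mask to the nearest
boundary voxel of the other.  Distances are measured in millimetres using
the voxel spacing, so with 1 mm isotropic voxels ASD is in voxel units.
Each direction is normalised by its own point count and the two directional
means are averaged with weight 1/2; the metric is therefore symmetric under
swapping prediction and truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "LabelVolume",
    "SurfacePointSet",
    "EmptyMaskError",
    "dice_score",
    "extract_surface",
    "asd",
    "mean_quality",
    "DEFAULT_LABEL_NAMES",
]

DEFAULT_LABEL_NAMES: Dict[int, str] = {0: "background", 1: "CSF", 2: "GM", 3: "WM"}


class EmptyMaskError(ValueError):
    """Raised when a surface-based metric meets an empty mask."""


@dataclass
class LabelVolume:
    """An integer tissue-label map over a 2D or 3D grid.

    ``spacing`` is the per-axis voxel size in mm (default 1.0 mm isotropic).
    """

    labels: np.ndarray
    spacing: Optional[Tuple[float, ...]] = None
    label_names: Dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_NAMES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        if self.spacing is None:
            self.spacing = (1.0,) * self.labels.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.labels.ndim:
            raise ValueError("spacing must have one entry per grid axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing entries must be strictly positive")

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.labels.shape


@dataclass
class SurfacePointSet:
    """Boundary voxel coordinates of one label region, with source spacing."""

    points: np.ndarray  # (n_points, ndim) integer voxel coordinates
    spacing: Tuple[float, ...]

    def __len__(self) -> int:
        return len(self.points)

    def physical(self) -> np.ndarray:
        """Coordinates scaled to millimetres."""
        return self.points * np.asarray(self.spacing)


def _check_grids(pred: LabelVolume, truth: LabelVolume) -> None:
    if pred.shape != truth.shape:
        raise ValueError(f"grid mismatch: prediction {pred.shape} vs truth {truth.shape}")


def dice_score(pred: LabelVolume, truth: LabelVolume, label: int) -> float:
    """Dice overlap ``2|S∩T| / (|S|+|T|)`` for one tissue label.

    When the label is absent from both volumes the masks are identical
    (both empty) and 1.0 is returned by convention.
    """
    _check_grids(pred, truth)
    s = pred.mask(label)
    t = truth.mask(label)
    denom = int(s.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(s, t).sum()) / denom


def _surface_mask(mask: np.ndarray) -> np.ndarray:
    # face connectivity (4-neighbourhood in 2D, 6 in 3D); border_value=0 makes
    # the grid edge count as outside, so voxels touching the edge are surface
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~interior


def extract_surface(volume: LabelVolume, label: int) -> SurfacePointSet:
    """Boundary voxels of one label: mask voxels with a face-adjacent
    neighbour outside the mask (grid edges count as outside)."""
    mask = volume.mask(label)
    if not mask.any():
        raise EmptyMaskError(f"label {label} has an empty mask; surface undefined")
    surf = _surface_mask(mask)
    points = np.argwhere(surf)
    return SurfacePointSet(points=points, spacing=volume.spacing)


def asd(pred: LabelVolume, truth: LabelVolume, label: int) -> float:
    """Average surface distance in mm between prediction and truth.

    Mean nearest-boundary distance from prediction surface to truth surface,
    averaged symmetrically with the reverse direction.  Raises
    :class:`EmptyMaskError` if either mask is empty.
    """
    _check_grids(pred, truth)
    s_mask = pred.mask(label)
    t_mask = truth.mask(label)
    if not s_mask.any() or not t_mask.any():
        raise EmptyMaskError(f"label {label} empty in prediction or truth; ASD undefined")
    s_surf = _surface_mask(s_mask)
    t_surf = _surface_mask(t_mask)
    spacing = pred.spacing
    # distance from every voxel to the nearest surface voxel of each set
    d_to_t = ndimage.distance_transform_edt(~t_surf, sampling=spacing)
    d_to_s = ndimage.distance_transform_edt(~s_surf, sampling=spacing)
    mean_s_to_t = float(d_to_t[s_surf].mean())
    mean_t_to_s = float(d_to_s[t_surf].mean())
    return 0.5 * (mean_s_to_t + mean_t_to_s)


def mean_quality(pred: LabelVolume, truth: LabelVolume, labels: Sequence[int]) -> float:
    """Unweighted mean of per-label Dice; the scalar environment response
    consumed by the configuration search."""
    labels = list(labels)
    if not labels:
        raise ValueError("labels must be a non-empty list")
    return float(np.mean([dice_score(pred, truth, lab) for lab in labels]))
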