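"""Cortical thickness and the size-normalized thickness index √A/Cth.

Cortical thickness (Cth) is the distance from the renal capsule to the
cortex–medulla border. It is measured in 2D on the central frontal slice,
at sites evenly spaced in polar angle around the slice centroid: from each
capsule point the profile runs inward until the grey value first drops below
the cortex-class threshold. The dimensionless index √A_kidney / Cth
normalizes thickness by organ size (√area and thickness both scale linearly
with the organ), so healthy kidneys of different sizes share a common index.

A 3D distance-transform thickness over ground-truth labels is provided as a
QC oracle; it is not the reported Cth, which is deliberately the 2D in-plane
quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volio import VoxelGrid
from .histoclass import ClassBoundaries
from .organmetrics import OrganMask

__all__ = ["ThicknessResult", "MorphoIndex", "cortical_thickness",
           "thickness_index", "label_thickness_3d"]


@dataclass
class ThicknessResult:
    site_distances_mm: list[float]
    n_sites: int
    slice_axis: int
    slice_index: int

    def __post_init__(self) -> None:
        if self.n_sites < 5:
            raise ValueError("thickness needs at least five measurement sites")
        if len(self.site_distances_mm) != self.n_sites:
            raise ValueError("site count mismatch")
        if any(d <= 0 for d in self.site_distances_mm):
            raise ValueError("all site distances must be positive")

    @property
    def mean_thickness_mm(self) -> float:
        return float(np.mean(self.site_distances_mm))


@dataclass
class MorphoIndex:
    a_kidney_mm2: float
    cth_mm: float

    def __post_init__(self) -> None:
        if self.a_kidney_mm2 <= 0 or self.cth_mm <= 0:
            raise ValueError("surface area and thickness must be positive")

    @property
    def index(self) -> float:
        return float(np.sqrt(self.a_kidney_mm2) / self.cth_mm)


def thickness_index(a_kidney_mm2: float, cth_mm: float) -> MorphoIndex:
    """Size-normalized cortical thickness index √A_kidney / Cth."""
    return MorphoIndex(float(a_kidney_mm2), float(cth_mm))


def cortical_thickness(
    grid: VoxelGrid,
    mask: OrganMask,
    boundaries: ClassBoundaries,
    n_sites: int = 8,
    seed: int | None = None,
    slice_axis: int = 1,
    slice_index: int | None = None,
) -> ThicknessResult:
    """Measure Cth on the central frontal slice.

    Sites sit at ``n_sites`` evenly spaced polar angles starting at
    12 o'clock around the in-slice organ centroid (deterministic; ``seed``
    is accepted for interface symmetry but unused). Each site is the capsule
    point where the ray exits the organ; its thickness is the in-plane
    distance from that point to the nearest interior voxel below the cortex
    threshold — the perpendicular capsule-to-medulla-border distance a
    caliper measurement on the slice would give, rather than the oblique
    ray length. Sites with no sub-threshold voxel in reach (the ray region
    never leaves the cortex class) are skipped with a warning; fewer than
    five valid sites is an error.
    """
    if n_sites < 5:
        raise ValueError("n_sites must be >= 5")
    if slice_axis not in (0, 1, 2):
        raise ValueError("slice_axis must be 0, 1 or 2")
    if grid.values.shape != mask.mask.shape:
        raise ValueError("grid and mask are not paired")

    thr = float(np.atleast_1d(boundaries.thresholds)[-1])
    sp = grid.spacing_mm

    # central slice: middle of the organ's bounding box along the slice axis
    occ = np.any(mask.mask, axis=tuple(i for i in range(3) if i != slice_axis))
    idx = np.flatnonzero(occ)
    if slice_index is None:
        slice_index = int((idx[0] + idx[-1]) // 2)
    plane_vals = np.take(grid.values, slice_index, axis=slice_axis).astype(float)
    plane_mask = np.take(mask.mask, slice_index, axis=slice_axis)
    if not plane_mask.any():
        raise ValueError("organ absent from the requested slice")

    cy, cx = ndimage.center_of_mass(plane_mask)
    max_t = float(np.hypot(*plane_mask.shape))  # voxels, generous upper bound
    step = 0.25  # voxels

    def sample(arr, py, px):
        return ndimage.map_coordinates(arr, [[py], [px]], order=1,
                                       mode="constant", cval=0.0)[0]

    # interior sub-cortical region: below-threshold voxels inside the organ
    # (medulla and cavities; the dark background is explicitly excluded)
    sub_cortex = (plane_vals < thr) & plane_mask
    if not sub_cortex.any():
        raise ValueError("no voxel below the cortex threshold inside the organ")
    dist_to_border = ndimage.distance_transform_edt(~sub_cortex, sampling=sp)

    distances: list[float] = []
    angles = -np.pi / 2 + 2 * np.pi * np.arange(n_sites) / n_sites  # 12 o'clock first
    fmask = plane_mask.astype(float)
    for th in angles:
        dy, dx = np.sin(th), np.cos(th)
        # outermost organ point along the ray = capsule site
        ts = np.arange(0.0, max_t, step)
        inside = np.array([sample(fmask, cy + t * dy, cx + t * dx) >= 0.5
                           for t in ts])
        hit = np.flatnonzero(inside)
        if len(hit) == 0:
            warnings.warn("ray misses the organ; site skipped")
            continue
        t_out = ts[hit[-1]]
        d = sample(dist_to_border, cy + t_out * dy, cx + t_out * dx)
        # a capsule site farther from any interior border than the organ is
        # wide has no medulla along its profile
        if d <= 0 or d > max_t * sp:
            warnings.warn("site ray never left the cortex class; site skipped")
            continue
        distances.append(float(d))

    if len(distances) < 5:
        raise ValueError(
            f"only {len(distances)} valid thickness sites (need >= 5)"
        )
    return ThicknessResult(distances, len(distances), slice_axis, slice_index)


def label_thickness_3d(cortex_mask: np.ndarray, spacing_mm: float) -> float:
    """QC oracle: 3D mean cortical thickness from a ground-truth cortex mask.

    Distance from the outer cortex boundary to the nearest non-cortex
    interior voxel, averaged over outer-boundary voxels.
    """
    cm = np.asarray(cortex_mask, dtype=bool)
    if not cm.any():
        raise ValueError("empty cortex mask")
    filled = ndimage.binary_fill_holes(cm)
    interior_non_cortex = filled & ~cm  # medulla + cavities
    if not interior_non_cortex.any():
        raise ValueError("cortex mask has no interior to measure against")
    dist_to_inner = ndimage.distance_transform_edt(
        ~interior_non_cortex, sampling=spacing_mm)
    outer_boundary = cm & ~ndimage.binary_erosion(filled)
    return float(dist_to_inner[outer_boundary].mean())
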