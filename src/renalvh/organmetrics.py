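"""Whole-organ segmentation, volumetry and surface area.

One organ per volume. Segmentation is threshold-based: voxels at or above
the threshold, reduced to the largest 26-connected component, with interior
holes filled in 3D — unstained cavities (pelvis, vessel lumina) lie inside
the organ and must count toward the whole-kidney volume, because the
histogram classification downstream expects them inside the organ VOI.

Surface area comes from a triangulated isosurface (marching cubes), not from
voxel-face counting: face counting overestimates a sphere's area by ~50%,
which would wreck any size-normalized thickness index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
import trimesh
from skimage import filters, measure

from .volio import VoxelGrid

__all__ = ["OrganMask", "segment_organ", "organ_volume", "organ_surface_area",
           "volume_change_percent"]


@dataclass
class OrganMask:
    """Boolean organ support paired to a grid (single connected component)."""

    mask: np.ndarray
    spacing_mm: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.mask.any():
            raise ValueError("empty segmentation")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def segment_organ(grid: VoxelGrid, threshold: float | str = "auto") -> OrganMask:
    """Threshold segmentation of the single organ in the field of view.

    ``threshold="auto"`` picks the two-class (Otsu) threshold between
    background and tissue. The result is the largest 26-connected
    above-threshold component with interior holes filled; a size tie between
    components is broken deterministically toward the component containing
    the smallest linear voxel index.
    """
    vals = grid.values
    if threshold == "auto":
        threshold = float(filters.threshold_otsu(vals))
    else:
        threshold = float(threshold)
    fg = vals >= threshold
    if not fg.any():
        raise ValueError(f"empty segmentation: no voxel >= threshold {threshold}")

    lab, n = ndimage.label(fg, structure=_STRUCT26)
    if n > 1:
        sizes = np.bincount(lab.ravel())[1:]
        best = np.flatnonzero(sizes == sizes.max()) + 1
        if len(best) > 1:
            # deterministic tie-break: smallest first linear index
            flat = lab.ravel()
            first = {b: np.argmax(flat == b) for b in best}
            keep = min(best, key=lambda b: first[b])
        else:
            keep = best[0]
        fg = lab == keep
    fg = ndimage.binary_fill_holes(fg)
    return OrganMask(fg, grid.spacing_mm)


def organ_volume(mask: OrganMask) -> float:
    """Volume in mm³: foreground voxel count × spacing³."""
    return mask.n_voxels * mask.spacing_mm ** 3


def organ_surface_area(mask: OrganMask) -> float:
    """Surface area in mm² of the triangulated mask isosurface."""
    m = mask.mask
    if (m[0].any() or m[-1].any() or m[:, 0].any() or m[:, -1].any()
            or m[:, :, 0].any() or m[:, :, -1].any()):
        warnings.warn("mask touches the grid border; surface is open there")
    padded = np.pad(m.astype(np.uint8), 1)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=(mask.spacing_mm,) * 3)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    # Taubin smoothing relaxes the voxel staircase (which inflates a
    # sphere's area by ~9%) without shrinking the mesh or bending flat
    # faces; the iteration count scales with mesh density so the smoothing
    # length is fixed in physical units and the estimate converges with
    # resolution
    iters = int(np.clip(round(1.6 / mask.spacing_mm), 10, 200))
    trimesh.smoothing.filter_taubin(mesh, iterations=iters)
    return float(mesh.area)


def volume_change_percent(v_reference_mm3: float, v_other_mm3: float) -> float:
    """Signed percent volume change of ``other`` relative to ``reference``.

    Positive for swelling, negative for shrinkage.
    """
    if v_reference_mm3 <= 0:
        raise ValueError("reference volume must be positive")
    return 100.0 * (v_other_mm3 - v_reference_mm3) / v_reference_mm3
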