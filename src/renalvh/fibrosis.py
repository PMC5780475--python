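"""Cortical radio-opacity statistics and two-group comparison.

Fibrotic remodeling after unilateral ureteral obstruction (UUO) reduces the
PTA uptake of the renal cortex, which reads out as lower grey values. The
sampling protocol places small cubes (default edge 0.5 mm, 0.125 mm³)
inside the cortex class, records each cube's minimum / mean / maximum grey
value, aggregates per kidney, and compares UUO against sham-operated
contralateral kidneys with an unpaired t-test. The statistical unit is the
kidney (the mean over its cube means), not the individual cube.

Cube placement is automated and reproducible: the cortex mask is eroded by
half the cube's space diagonal, the first center is the deepest point of
the eroded region, and the remaining centers follow farthest-point sampling
— a deterministic, documented realization of "evenly distributed" sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .volio import VoxelGrid

__all__ = ["CubeROI", "CubeStats", "GroupComparison", "place_cortical_cubes",
           "cube_grey_stats", "whole_cortex_stats", "unpaired_t_test",
           "cortical_volume_loss"]


@dataclass
class CubeROI:
    """An axis-aligned sampling cube, physical coordinates in mm."""

    center_mm: tuple[float, float, float]
    edge_mm: float = 0.5

    def __post_init__(self) -> None:
        if self.edge_mm <= 0:
            raise ValueError("edge must be positive")
        self.center_mm = tuple(float(c) for c in self.center_mm)

    @property
    def volume_mm3(self) -> float:
        return self.edge_mm ** 3


@dataclass
class CubeStats:
    """Per-cube min/mean/max grey values plus per-kidney aggregates."""

    min_gv: list[float]
    mean_gv: list[float]
    max_gv: list[float]

    def __post_init__(self) -> None:
        if not (len(self.min_gv) == len(self.mean_gv) == len(self.max_gv)):
            raise ValueError("per-cube lists must have equal length")
        for lo, mid, hi in zip(self.min_gv, self.mean_gv, self.max_gv):
            if not lo <= mid <= hi:
                raise ValueError("each cube must satisfy min <= mean <= max")

    @property
    def n_cubes(self) -> int:
        return len(self.mean_gv)

    @property
    def aggregate_mean_gv(self) -> float:
        """Kidney-level radio-opacity: mean of the cube means."""
        return float(np.mean(self.mean_gv))

    @property
    def aggregate_max_gv(self) -> float:
        """Kidney-level peak radio-opacity: max of the cube maxima."""
        return float(np.max(self.max_gv))


@dataclass
class GroupComparison:
    group_names: tuple[str, str]
    mean: tuple[float, float]
    sd: tuple[float, float]
    n: tuple[int, int]
    t_statistic: float
    df: float
    p_value: float
    equal_var: bool

    def to_dict(self) -> dict:
        return {
            "groups": list(self.group_names),
            "mean": list(self.mean),
            "sd": list(self.sd),
            "n": list(self.n),
            "t": self.t_statistic,
            "df": self.df,
            "p": self.p_value,
            "variance_assumption": "pooled" if self.equal_var else "welch",
        }


def place_cortical_cubes(
    cortex_mask: np.ndarray,
    spacing_mm: float,
    edge_mm: float = 0.5,
    n_cubes: int = 6,
    seed: int | None = None,
) -> list[CubeROI]:
    """Place ``n_cubes`` fully contained cubes evenly through the cortex.

    Feasible centers are voxels whose distance to the cortex-class boundary
    is at least half the cube's space diagonal. The first center maximizes
    that distance; subsequent centers maximize the minimum distance to the
    already chosen ones (farthest-point sampling). Deterministic; ``seed``
    is accepted for interface symmetry. Raises if the cortex is too thin,
    reporting the largest feasible edge.
    """
    cm = np.asarray(cortex_mask, dtype=bool)
    if not cm.any():
        raise ValueError("empty cortex mask")
    if n_cubes < 1:
        raise ValueError("n_cubes must be >= 1")
    if edge_mm <= 2 * spacing_mm:
        raise ValueError("cube edge must exceed two voxel spacings")

    half_diag = edge_mm * np.sqrt(3.0) / 2.0
    depth = ndimage.distance_transform_edt(cm, sampling=spacing_mm)
    feasible = depth >= half_diag
    if not feasible.any():
        max_edge = 2.0 * float(depth.max()) / np.sqrt(3.0)
        raise ValueError(
            f"cortex too thin for edge {edge_mm} mm; "
            f"largest feasible edge is {max_edge:.3f} mm"
        )

    cand = np.argwhere(feasible)
    cand_mm = (cand + 0.5) * spacing_mm
    first = int(np.argmax(depth[feasible.nonzero()]))
    chosen = [first]
    dmin = np.linalg.norm(cand_mm - cand_mm[first], axis=1)
    for _ in range(1, n_cubes):
        nxt = int(np.argmax(dmin))  # argmax is deterministic on ties
        chosen.append(nxt)
        dmin = np.minimum(dmin, np.linalg.norm(cand_mm - cand_mm[nxt], axis=1))

    cubes = [CubeROI(tuple(cand_mm[i]), edge_mm) for i in chosen]
    for cube in cubes:
        sl = _cube_slices(cube, spacing_mm, cm.shape)
        if not cm[sl].all():
            raise RuntimeError(
                f"containment check failed for cube at {cube.center_mm}"
            )
    return cubes


def _cube_slices(cube: CubeROI, spacing_mm: float, shape) -> tuple[slice, ...]:
    """Index slices of voxels whose centers lie inside the cube."""
    out = []
    for c, n in zip(cube.center_mm, shape):
        lo = c - cube.edge_mm / 2.0
        hi = c + cube.edge_mm / 2.0
        # voxel center (i + 0.5) * spacing in [lo, hi)
        i0 = max(0, int(np.ceil(lo / spacing_mm - 0.5)))
        i1 = min(n, int(np.floor(hi / spacing_mm - 0.5)) + 1)
        if i1 <= i0:
            raise ValueError("cube contains no voxel centers")
        out.append(slice(i0, i1))
    return tuple(out)


def cube_grey_stats(grid: VoxelGrid, cubes: list[CubeROI]) -> CubeStats:
    """Min/mean/max grey value over the voxel centers inside each cube."""
    mins, means, maxs = [], [], []
    for cube in cubes:
        sl = _cube_slices(cube, grid.spacing_mm, grid.values.shape)
        vals = grid.values[sl].astype(float)
        mins.append(float(vals.min()))
        means.append(float(vals.mean()))
        maxs.append(float(vals.max()))
    return CubeStats(mins, means, maxs)


def whole_cortex_stats(grid: VoxelGrid, cortex_class_mask: np.ndarray) -> dict:
    """Grey-value statistics and volume over all cortex-class voxels."""
    cm = np.asarray(cortex_class_mask, dtype=bool)
    if cm.shape != grid.values.shape:
        raise ValueError("mask geometry does not match grid")
    if not cm.any():
        raise ValueError("empty cortex mask")
    vals = grid.values[cm].astype(float)
    return {
        "mean_gv": float(vals.mean()),
        "sd_gv": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        "max_gv": float(vals.max()),
        "n_voxels": int(vals.size),
        "volume_mm3": float(vals.size) * grid.voxel_volume_mm3,
    }


def unpaired_t_test(
    a=None,
    b=None,
    *,
    summary_a: tuple[float, float, int] | None = None,
    summary_b: tuple[float, float, int] | None = None,
    equal_var: bool = True,
    group_names: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-sided unpaired t-test on raw values or (mean, sd, n) summaries.

    Student's pooled-variance test by default; Welch via
    ``equal_var=False``. SDs use the n−1 denominator. Degenerate case —
    zero pooled variance with equal means — returns t = 0, p = 1.
    """
    if (a is None) != (b is None) or (summary_a is None) != (summary_b is None):
        raise ValueError("provide both groups, either raw or as summaries")
    if a is not None:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need n >= 2 per group")
        summary_a = (float(a.mean()), float(a.std(ddof=1)), len(a))
        summary_b = (float(b.mean()), float(b.std(ddof=1)), len(b))
    elif summary_a is None:
        raise ValueError("no data given")

    m1, s1, n1 = summary_a
    m2, s2, n2 = summary_b
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")

    if s1 == 0.0 and s2 == 0.0:
        if m1 == m2:
            df = float(n1 + n2 - 2)
            return GroupComparison(group_names, (m1, m2), (s1, s2), (n1, n2),
                                   0.0, df, 1.0, equal_var)
        raise ValueError("zero variance with unequal means: t is undefined")

    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2,
                                     equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return GroupComparison(group_names, (m1, m2), (s1, s2), (n1, n2),
                           float(res.statistic), df, float(res.pvalue),
                           equal_var)


def cortical_volume_loss(v_cortex_uuo_mm3: float, v_cortex_sham_mm3: float) -> float:
    """Percent cortical mass lost in the obstructed kidney vs its control.

    Assumes both kidneys of one animal started at the same volume, so the
    contralateral sham cortex is the baseline.
    """
    if v_cortex_sham_mm3 <= 0:
        raise ValueError("sham cortex volume must be positive")
    return 100.0 * (1.0 - v_cortex_uuo_mm3 / v_cortex_sham_mm3)
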