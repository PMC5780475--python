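"""Synthetic PTA-stained kidney phantoms with known ground truth.

A phosphotungstic-acid (PTA) stained kidney in a micro-CT scan shows a
characteristic concentric stratification: a bright outer cortex (dense
tissue, high PTA uptake), a dimmer medulla, and a nearly unstained pelvis /
cavity core at air-like grey values, all embedded in a dark background.
The phantom reproduces exactly the *statistical* structure the downstream
analysis assumes — per-compartment Gaussian grey-value distributions with
the ordering cortex > medulla > pelvis — on an analytically known geometry
(nested similar ellipsoids), so that every quantification stage can be
tested against exact voxel-count ground truth instead of scan data.

Pathology support mirrors the two remodeling scenarios of interest:

* ``uuo`` — unilateral ureteral obstruction: the pelvis dilates, medullary
  structure is extinguished (reassigned to cavity), and cortical grey
  values drop by a fixed radio-opacity shift (the fibrosis signal).
* ``cyst`` — spherical unstained cavities carved out of the parenchyma.

No x-ray physics or PTA diffusion kinetics are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volio import VoxelGrid
from .histoclass import CompartmentReport

__all__ = [
    "AIR", "PELVIS", "MEDULLA", "CORTEX", "VESSEL", "CYST",
    "LABEL_LEGEND", "PhantomSpec", "PathologySpec", "LabelGrid",
    "generate_kidney_phantom", "apply_pathology", "phantom_truth_report",
]

AIR, PELVIS, MEDULLA, CORTEX, VESSEL, CYST = 0, 1, 2, 3, 4, 5
LABEL_LEGEND = {
    AIR: "air", PELVIS: "pelvis", MEDULLA: "medulla",
    CORTEX: "cortex", VESSEL: "vessel", CYST: "cyst",
}
#: labels pooled into the lowest grey-value class for volumetry: cavities and
#: unstained vessel lumina count with the pelvis, never with parenchyma
_PELVIS_CLASS = (PELVIS, VESSEL, CYST)

_GV_MAX = 65535.0


@dataclass
class LabelGrid:
    """Per-voxel compartment labels paired to a :class:`VoxelGrid`."""

    labels: np.ndarray
    spacing_mm: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label_legend: dict = field(default_factory=lambda: dict(LABEL_LEGEND))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")

    @property
    def shape(self):
        return self.labels.shape

    def organ_mask(self) -> np.ndarray:
        return self.labels != AIR

    def compartment_mask(self, name: str) -> np.ndarray:
        """Boolean mask of one grey-value class (pelvis pools cavities)."""
        if name == "pelvis":
            return np.isin(self.labels, _PELVIS_CLASS)
        inv = {v: k for k, v in self.label_legend.items()}
        if name not in inv:
            raise KeyError(f"unknown compartment {name!r}")
        return self.labels == inv[name]


@dataclass
class PathologySpec:
    """Descriptor of a remodeling scenario applied to a healthy phantom."""

    kind: str  # "uuo" or "cyst"
    pelvis_dilation_factor: float = 1.0
    medulla_retention: float = 1.0
    cortex_gv_shift: float = 0.0
    cyst_centers_mm: list[tuple[float, float, float]] = field(default_factory=list)
    cyst_radii_mm: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("uuo", "cyst"):
            raise ValueError(f"kind must be 'uuo' or 'cyst', got {self.kind!r}")
        if self.pelvis_dilation_factor < 1:
            raise ValueError("pelvis_dilation_factor must be >= 1")
        if not 0.0 <= self.medulla_retention <= 1.0:
            raise ValueError("medulla_retention must be in [0, 1]")
        if len(self.cyst_centers_mm) != len(self.cyst_radii_mm):
            raise ValueError("cyst centers and radii must have equal length")


@dataclass
class PhantomSpec:
    """Parameters of one synthetic kidney.

    Defaults emulate a healthy adult murine kidney at scanner scale:
    ellipsoid semi-axes 5.2/3.4/2.9 mm (whole-organ volume ~215 mm³),
    compartment volume fractions pelvis/medulla/cortex = 0.12/0.16/0.72,
    and grey-value classes pelvis ≈ 500, medulla ≈ 2500, cortex ≈ 3575
    detector units, with the cortical spread (94.5 GV) at the scale of
    measured healthy cortical radio-opacity. Voxel spacing 0.04 mm matches
    the coarser of the two scanner settings the pipeline targets (0.04 and
    0.0125 mm).
    """

    voxel_spacing_mm: float = 0.04
    organ_semi_axes_mm: tuple[float, float, float] = (5.2, 3.4, 2.9)
    compartment_fractions: tuple[float, float, float] = (0.12, 0.16, 0.72)
    compartment_gv: dict = field(default_factory=lambda: {
        "pelvis": (500.0, 80.0),
        "medulla": (2500.0, 150.0),
        "cortex": (3575.0, 94.5),
    })
    noise_sd: float = 0.0
    background_gv: tuple[float, float] = (100.0, 30.0)
    pathology: PathologySpec | None = None
    seed: int = 0
    margin_mm: float = 0.4
    n_vessels: int = 0
    vessel_radius_mm: float = 0.06
    glomerular_dots: bool = False

    def __post_init__(self) -> None:
        f = np.asarray(self.compartment_fractions, dtype=float)
        if f.shape != (3,):
            raise ValueError("compartment_fractions must be (pelvis, medulla, cortex)")
        if np.any(f <= 0) or np.any(f >= 1):
            raise ValueError("fractions must lie in (0, 1)")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {f.sum()}")
        if self.voxel_spacing_mm <= 0:
            raise ValueError("voxel_spacing_mm must be positive")
        axes = np.asarray(self.organ_semi_axes_mm, dtype=float)
        if axes.shape != (3,) or np.any(axes <= 0):
            raise ValueError("organ_semi_axes_mm must be three positive lengths")
        if np.any(axes <= 2 * self.voxel_spacing_mm):
            raise ValueError("semi-axes must exceed 2 voxel spacings")
        for name in ("pelvis", "medulla", "cortex"):
            if name not in self.compartment_gv:
                raise ValueError(f"compartment_gv missing {name!r}")
            mean, sd = self.compartment_gv[name]
            if not 0 <= mean <= _GV_MAX:
                raise ValueError(f"{name} mean GV {mean} outside [0, {_GV_MAX:.0f}]")
            if sd < 0:
                raise ValueError(f"{name} SD must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.background_gv[1] < 0:
            raise ValueError("background SD must be >= 0")

    # -- shell geometry -----------------------------------------------------
    # Nested similar ellipsoids: the volume fraction inside linear scale s is
    # s**3, so target fractions map to scales by a cube root.

    @property
    def shell_scales(self) -> tuple[float, float]:
        """Linear scales (s_pelvis, s_medulla_outer) of the inner shells."""
        f_p, f_m, _ = self.compartment_fractions
        return float(np.cbrt(f_p)), float(np.cbrt(f_p + f_m))

    def to_json(self, path: str | Path) -> None:
        d = {k: getattr(self, k) for k in (
            "voxel_spacing_mm", "organ_semi_axes_mm", "compartment_fractions",
            "compartment_gv", "noise_sd", "background_gv", "seed", "margin_mm",
            "n_vessels", "vessel_radius_mm", "glomerular_dots")}
        d["organ_semi_axes_mm"] = list(d["organ_semi_axes_mm"])
        d["compartment_fractions"] = list(d["compartment_fractions"])
        d["background_gv"] = list(d["background_gv"])
        d["compartment_gv"] = {k: list(v) for k, v in d["compartment_gv"].items()}
        if self.pathology is not None:
            d["pathology"] = {
                "kind": self.pathology.kind,
                "pelvis_dilation_factor": self.pathology.pelvis_dilation_factor,
                "medulla_retention": self.pathology.medulla_retention,
                "cortex_gv_shift": self.pathology.cortex_gv_shift,
                "cyst_centers_mm": [list(c) for c in self.pathology.cyst_centers_mm],
                "cyst_radii_mm": list(self.pathology.cyst_radii_mm),
            }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        with open(path) as fh:
            d = json.load(fh)
        if "pathology" in d and d["pathology"] is not None:
            p = d["pathology"]
            p["cyst_centers_mm"] = [tuple(c) for c in p.get("cyst_centers_mm", [])]
            d["pathology"] = PathologySpec(**p)
        for key in ("organ_semi_axes_mm", "compartment_fractions", "background_gv"):
            if key in d:
                d[key] = tuple(d[key])
        if "compartment_gv" in d:
            d["compartment_gv"] = {k: tuple(v) for k, v in d["compartment_gv"].items()}
        return cls(**d)


def _ellipsoid_rho(shape, spacing, semi_axes, center_mm) -> np.ndarray:
    """Normalized ellipsoid radius of every voxel center (<= 1 inside)."""
    coords = [
        ((np.arange(n) + 0.5) * spacing - c) / a
        for n, c, a in zip(shape, center_mm, semi_axes)
    ]
    zz = coords[0][:, None, None] ** 2
    yy = coords[1][None, :, None] ** 2
    xx = coords[2][None, None, :] ** 2
    return np.sqrt(zz + yy + xx)


def _draw_gv(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    vals = rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, mean)
    return vals


def generate_kidney_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, LabelGrid]:
    """Build one synthetic kidney volume plus its ground-truth labels.

    Deterministic under ``spec.seed``. Raises on degenerate geometry (any
    compartment shell thinner than one voxel along the shortest axis).
    """
    s_p, s_m = spec.shell_scales
    axes = np.asarray(spec.organ_semi_axes_mm, float)
    min_ax = axes.min()
    sp = spec.voxel_spacing_mm
    if min_ax * (1.0 - s_m) < sp or min_ax * (s_m - s_p) < sp or min_ax * s_p < sp:
        raise ValueError(
            "degenerate geometry: a compartment shell is thinner than one voxel "
            f"(spacing {sp} mm, shell thicknesses "
            f"{min_ax * s_p:.4f}/{min_ax * (s_m - s_p):.4f}/{min_ax * (1 - s_m):.4f} mm)"
        )

    half = axes + spec.margin_mm
    shape = tuple(int(np.ceil(2 * h / sp)) for h in half)
    center = tuple(n * sp / 2.0 for n in shape)
    rho = _ellipsoid_rho(shape, sp, axes, center)

    labels = np.full(shape, AIR, dtype=np.uint8)
    labels[rho <= 1.0] = CORTEX
    labels[rho <= s_m] = MEDULLA
    labels[rho <= s_p] = PELVIS

    rng = np.random.default_rng(spec.seed)

    if spec.n_vessels:
        _carve_vessels(labels, spec, axes, center, rng)

    values = np.empty(shape, dtype=np.float64)
    bg_mean, bg_sd = spec.background_gv
    values[labels == AIR] = _draw_gv(rng, int((labels == AIR).sum()), bg_mean, bg_sd)
    gv_of = {PELVIS: "pelvis", MEDULLA: "medulla", CORTEX: "cortex",
             VESSEL: "pelvis"}
    for lab, name in gv_of.items():
        m = labels == lab
        n = int(m.sum())
        if n:
            mean, sd = spec.compartment_gv[name]
            values[m] = _draw_gv(rng, n, mean, sd)

    if spec.glomerular_dots:
        _add_glomerular_dots(values, labels, spec, rng)

    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, size=shape)
    np.clip(values, 0.0, _GV_MAX, out=values)

    grid = VoxelGrid(values.astype(np.float32), sp)
    lab_grid = LabelGrid(labels, sp)

    if spec.pathology is not None:
        grid, lab_grid = apply_pathology(grid, lab_grid, spec.pathology,
                                         seed=spec.seed + 1)
    return grid, lab_grid


def _carve_vessels(labels, spec, axes, center, rng) -> None:
    """Unstained vessel lumina: straight dark cylinders through the cortex."""
    sp = spec.voxel_spacing_mm
    shape = labels.shape
    zc = (np.arange(shape[0]) + 0.5) * sp
    yc = (np.arange(shape[1]) + 0.5) * sp
    xc = (np.arange(shape[2]) + 0.5) * sp
    Z, Y, X = np.meshgrid(zc, yc, xc, indexing="ij")
    pts = np.stack([Z, Y, X], axis=-1)
    organ = labels != AIR
    for _ in range(spec.n_vessels):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        # anchor at a random point between the hilus region and mid-cortex
        t = rng.uniform(0.2, 0.8)
        anchor = np.asarray(center) + t * u * axes
        d = pts - anchor
        # distance of each voxel center to the line anchor + s*u
        proj = d @ u
        perp2 = np.einsum("...i,...i", d, d) - proj ** 2
        tube = (perp2 <= spec.vessel_radius_mm ** 2) & organ
        labels[tube & (labels == CORTEX)] = VESSEL
        labels[tube & (labels == MEDULLA)] = VESSEL


def _add_glomerular_dots(values, labels, spec, rng) -> None:
    """Fine structure: dark dots 50-100 µm across, visible only at 12.5 µm."""
    cortex_idx = np.argwhere(labels == CORTEX)
    if not len(cortex_idx):
        return
    n_dots = max(1, len(cortex_idx) // 5000)
    picks = cortex_idx[rng.choice(len(cortex_idx), size=n_dots, replace=False)]
    rad_vox = rng.uniform(0.025, 0.05, size=n_dots) / spec.voxel_spacing_mm
    pel_mean = spec.compartment_gv["pelvis"][0]
    for (z, y, x), r in zip(picks, rad_vox):
        r = max(1, int(round(r)))
        zs, ys, xs = (slice(max(0, c - r), c + r + 1) for c in (z, y, x))
        sub = labels[zs, ys, xs] == CORTEX
        values[zs, ys, xs][sub] = pel_mean

def apply_pathology(
    grid: VoxelGrid,
    labels: LabelGrid,
    path: PathologySpec | None,
    seed: int = 0,
) -> tuple[VoxelGrid, LabelGrid]:
    """Apply a remodeling scenario, returning new (grid, labels).

    ``None`` is the identity. UUO dilates the pelvis cavity into the medulla,
    extinguishes the non-retained medulla (reassigned to cavity with
    pelvis-like grey values resampled from the phantom's own pelvis
    distribution), and shifts cortical grey values by ``cortex_gv_shift``.
    Cysts become cavity-label spheres; a cyst reaching outside the organ is
    rejected.
    """
    if path is None:
        return (VoxelGrid(grid.values.copy(), grid.spacing_mm, grid.origin_mm),
                LabelGrid(labels.labels.copy(), labels.spacing_mm,
                          labels.origin_mm, dict(labels.label_legend)))
    if grid.values.shape != labels.labels.shape or grid.spacing_mm != labels.spacing_mm:
        raise ValueError("grid and labels are not paired (shape/spacing mismatch)")

    rng = np.random.default_rng(seed)
    values = grid.values.astype(np.float64, copy=True)
    lab = labels.labels.copy()

    pel_mask = lab == PELVIS
    if pel_mask.any():
        pel_mean = float(values[pel_mask].mean())
        pel_sd = float(values[pel_mask].std())
    else:
        pel_mean, pel_sd = float(values[lab == AIR].mean()), float(values[lab == AIR].std())

    if path.kind == "uuo":
        med_mask = lab == MEDULLA
        n_med = int(med_mask.sum())
        n_pel = int(pel_mask.sum())
        if n_med:
            # distance of each medulla voxel from the existing cavity: the
            # cavity grows outward, the outermost medulla survives longest
            dist = ndimage.distance_transform_edt(~pel_mask,
                                                  sampling=grid.spacing_mm)
            med_idx = np.flatnonzero(med_mask.ravel())
            order = np.argsort(dist.ravel()[med_idx], kind="stable")
            n_dilate = min(n_med, int(round((path.pelvis_dilation_factor - 1.0) * n_pel)))
            n_keep = int(round(path.medulla_retention * n_med))
            n_convert = max(n_dilate, n_med - n_keep)
            if n_convert > 0:
                conv = med_idx[order[:n_convert]]
                flat_lab = lab.ravel()
                flat_lab[conv] = PELVIS
                flat_val = values.ravel()
                flat_val[conv] = rng.normal(pel_mean, max(pel_sd, 1e-12), size=n_convert)
        cor_mask = lab == CORTEX
        values[cor_mask] += path.cortex_gv_shift
    elif path.kind == "cyst":
        organ = lab != AIR
        sp = grid.spacing_mm
        for (cz, cy, cx), r in zip(path.cyst_centers_mm, path.cyst_radii_mm):
            coords = [
                (np.arange(n) + 0.5) * sp - c
                for n, c in zip(lab.shape, (cz, cy, cx))
            ]
            d2 = (coords[0][:, None, None] ** 2 + coords[1][None, :, None] ** 2
                  + coords[2][None, None, :] ** 2)
            sphere = d2 <= r ** 2
            if not sphere.any():
                raise ValueError(f"cyst at {(cz, cy, cx)} r={r} contains no voxel")
            if np.any(sphere & ~organ):
                raise ValueError(
                    f"cyst at {(cz, cy, cx)} r={r} mm extends outside the organ"
                )
            lab[sphere] = CYST
            values[sphere] = rng.normal(pel_mean, max(pel_sd, 1e-12),
                                        size=int(sphere.sum()))

    np.clip(values, 0.0, _GV_MAX, out=values)
    return (VoxelGrid(values.astype(np.float32), grid.spacing_mm, grid.origin_mm),
            LabelGrid(lab, labels.spacing_mm, labels.origin_mm,
                      dict(labels.label_legend)))


def phantom_truth_report(labels: LabelGrid) -> CompartmentReport:
    """Exact voxel-count compartment volumetry from ground-truth labels.

    Cavity-type labels (pelvis, vessel lumina, cysts) pool into the pelvis
    class, matching how the grey-value classification counts them.
    """
    vox = labels.spacing_mm ** 3
    n_pel = int(np.isin(labels.labels, _PELVIS_CLASS).sum())
    n_med = int((labels.labels == MEDULLA).sum())
    n_cor = int((labels.labels == CORTEX).sum())
    n_org = n_pel + n_med + n_cor
    if n_org == 0:
        raise ValueError("label grid contains no organ voxels")
    return CompartmentReport(
        v_kidney_mm3=n_org * vox,
        v_pelvis_mm3=n_pel * vox,
        v_medulla_mm3=n_med * vox,
        v_cortex_mm3=n_cor * vox,
    )
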