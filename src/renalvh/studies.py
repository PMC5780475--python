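"""Validation studies: parameter recovery, detection power, specificity.

The printed group results the pipeline is meant to reproduce (cortical
grey-value depression after ureteral obstruction, compartment fractions)
came from scans that are not shipped; these studies re-create the *study
conditions* on synthetic kidneys — paper-scale grey-value classes and
spreads, four kidneys per group, six cortical cubes per kidney — and
measure what the pipeline recovers. Phantom geometry is scaled down
(ellipsoid semi-axes ~2.4/1.8/1.5 mm, 80 µm voxels, 0.25 mm cubes) so a
full replicate stays well under a second; grey-value parameters are never
scaled.

Every function is deterministic under its ``seed`` and runs the real
pipeline end to end (segmentation → histogram → mixture → boundaries →
classification → cubes); nothing is read off the ground-truth labels except
where a function is explicitly the truth oracle.
"""

from __future__ import annotations

import numpy as np

from . import fibrosis, histoclass, organmetrics
from .phantom import (PathologySpec, PhantomSpec, generate_kidney_phantom,
                      phantom_truth_report)

__all__ = [
    "SIM_GEOMETRY", "UUO_PATHOLOGY", "kidney_cube_mean",
    "fibrosis_group_pvalue", "fibrosis_power_study", "sham_fpr_study",
    "fraction_recovery_study",
]

#: scaled-down study geometry (mm); grey-value parameters stay at scan scale
SIM_GEOMETRY = {
    "voxel_spacing_mm": 0.08,
    "organ_semi_axes_mm": (2.4, 1.8, 1.5),
    "cube_edge_mm": 0.25,
    "n_cubes": 6,
}

#: obstructed-kidney remodeling: dilated pelvis, near-complete medullary
#: extinction, cortical radio-opacity depressed by the difference of the
#: measured group means (3039 - 3575 GV)
UUO_PATHOLOGY = PathologySpec(
    kind="uuo",
    pelvis_dilation_factor=1.5,
    medulla_retention=0.2,
    cortex_gv_shift=-536.0,
)


def _phantom_spec(seed: int, pathology: PathologySpec | None = None,
                  fractions=(0.12, 0.16, 0.72)) -> PhantomSpec:
    return PhantomSpec(
        voxel_spacing_mm=SIM_GEOMETRY["voxel_spacing_mm"],
        organ_semi_axes_mm=SIM_GEOMETRY["organ_semi_axes_mm"],
        compartment_fractions=fractions,
        pathology=pathology,
        seed=seed,
    )


def kidney_cube_mean(seed: int, pathology: PathologySpec | None = None) -> float:
    """Aggregate cortical cube mean GV of one phantom, via the full pipeline."""
    grid, _ = generate_kidney_phantom(_phantom_spec(seed, pathology))
    mask = organmetrics.segment_organ(grid, "auto")
    hist = histoclass.compute_histogram(grid, mask.mask)
    model = histoclass.fit_mixture(hist, 3)
    bounds = histoclass.envelope_inflections(hist, model)
    cortex = histoclass.class_masks(grid, mask.mask, bounds)["cortex"]
    cubes = fibrosis.place_cortical_cubes(
        cortex, grid.spacing_mm, SIM_GEOMETRY["cube_edge_mm"],
        SIM_GEOMETRY["n_cubes"])
    return fibrosis.cube_grey_stats(grid, cubes).aggregate_mean_gv


def fibrosis_group_pvalue(seed: int, n_per_group: int = 4,
                          pathology_b: PathologySpec | None = UUO_PATHOLOGY
                          ) -> float:
    """One sham-vs-X comparison (X = UUO by default, sham under the null)."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=2 * n_per_group)
    sham = [kidney_cube_mean(int(s)) for s in seeds[:n_per_group]]
    other = [kidney_cube_mean(int(s), pathology_b) for s in seeds[n_per_group:]]
    return fibrosis.unpaired_t_test(sham, other).p_value


def fibrosis_power_study(n_replicates: int = 100, seed: int = 0,
                         alpha: float = 0.01) -> float:
    """Fraction of 4-vs-4 sham/UUO replicates detected at ``alpha``."""
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2 ** 31 - 1, size=n_replicates)
    hits = sum(fibrosis_group_pvalue(int(s)) < alpha for s in rep_seeds)
    return hits / n_replicates


def sham_fpr_study(n_replicates: int = 200, seed: int = 0,
                   alpha: float = 0.05) -> float:
    """False-positive rate of sham-vs-sham comparisons at ``alpha``."""
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2 ** 31 - 1, size=n_replicates)
    hits = sum(fibrosis_group_pvalue(int(s), pathology_b=None) < alpha
               for s in rep_seeds)
    return hits / n_replicates


def fraction_recovery_study(n_phantoms: int = 20, seed: int = 0,
                            cortex_range: tuple[float, float] = (0.60, 0.80)
                            ) -> dict:
    """Compartment-fraction recovery across phantoms of varying cortex share.

    Cortex fractions span ``cortex_range``; the remainder splits between
    pelvis and medulla at the healthy 12:16 ratio. Returns the mean absolute
    error (percentage points) of the pipeline's fractions against the
    ground-truth labels, with per-phantom details.
    """
    rng = np.random.default_rng(seed)
    cortex_fracs = np.linspace(*cortex_range, n_phantoms)
    errors = []
    rows = []
    for fc in cortex_fracs:
        rest = 1.0 - fc
        fractions = (rest * 12 / 28, rest * 16 / 28, fc)
        spec = _phantom_spec(int(rng.integers(0, 2 ** 31 - 1)),
                             fractions=fractions)
        grid, labels = generate_kidney_phantom(spec)
        truth = phantom_truth_report(labels).fractions_percent

        mask = organmetrics.segment_organ(grid, "auto")
        hist = histoclass.compute_histogram(grid, mask.mask)
        model = histoclass.fit_mixture(hist, 3)
        bounds = histoclass.envelope_inflections(hist, model)
        est = histoclass.compartment_volumes(hist, bounds).fractions_percent

        err = [abs(est[k] - truth[k]) for k in ("pelvis", "medulla", "cortex")]
        errors.extend(err)
        rows.append({"cortex_target": fc, **{f"err_{k}": e for k, e in
                                             zip(("pelvis", "medulla", "cortex"), err)}})
    return {"mean_abs_error_pp": float(np.mean(errors)),
            "max_abs_error_pp": float(np.max(errors)),
            "per_phantom": rows}
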