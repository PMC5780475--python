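"""One-call quantification of a kidney volume and cohort comparison.

``quantify_kidney`` chains the full virtual-histology analysis: organ
segmentation → grey-value histogram → Gaussian-class decomposition →
inflection-point boundaries → compartment volumetry → cortical thickness →
surface area → thickness index → whole-cortex radio-opacity (→ cortical
cube statistics when the cortex is thick enough for the configured cube).
Every tunable lives in one config mapping and is recorded in the report, so
each number is recomputable from the stored inputs plus stored settings.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .volio import VoxelGrid, read_volume
from . import histoclass, organmetrics, morpho, fibrosis

__all__ = ["DEFAULT_CONFIG", "AnalysisReport", "quantify_kidney",
           "compare_cohorts", "COHORT_METRICS", "validate_report_dict"]

log = logging.getLogger("renalvh")

#: every tunable of the pipeline; CLI flags and user configs override these
DEFAULT_CONFIG: dict = {
    "organ_threshold": "auto",   # grey value, or "auto" for Otsu
    "histogram_bins": 256,
    "n_classes": 3,              # organ-masked histogram: pelvis/medulla/cortex
    "boundary_method": "fitted_envelope",
    "n_thickness_sites": 8,
    "thickness_slice_axis": 1,
    "cube_edge_mm": 0.5,
    "n_cubes": 6,
    "seed": 0,
}


@dataclass
class AnalysisReport:
    """Full per-kidney quantification with provenance."""

    v_kidney_mm3: float
    compartments: dict
    cth_mm: float
    site_distances_mm: list[float]
    a_kidney_mm2: float
    index: float
    cortex_stats: dict
    cube_stats: dict | None
    mixture: dict
    thresholds: list[float]
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "V_kidney_mm3": self.v_kidney_mm3,
            "compartments": self.compartments,
            "Cth_mm": self.cth_mm,
            "site_distances_mm": self.site_distances_mm,
            "A_kidney_mm2": self.a_kidney_mm2,
            "index_sqrtA_over_Cth": self.index,
            "cortex_stats": self.cortex_stats,
            "cube_stats": self.cube_stats,
            "mixture": self.mixture,
            "thresholds_gv": self.thresholds,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def metric(self, name: str) -> float:
        try:
            return _METRIC_GETTERS[name](self)
        except KeyError:
            raise KeyError(
                f"unknown metric {name!r}; valid metrics: {sorted(_METRIC_GETTERS)}"
            ) from None


_METRIC_GETTERS = {
    "cube_mean_gv": lambda r: r.cube_stats["aggregate_mean_gv"],
    "cube_max_gv": lambda r: r.cube_stats["aggregate_max_gv"],
    "cortex_mean_gv": lambda r: r.cortex_stats["mean_gv"],
    "cortex_max_gv": lambda r: r.cortex_stats["max_gv"],
    "cortex_volume_mm3": lambda r: r.compartments["V_cortex_mm3"],
    "v_kidney_mm3": lambda r: r.v_kidney_mm3,
    "cth_mm": lambda r: r.cth_mm,
    "index": lambda r: r.index,
}

COHORT_METRICS = tuple(sorted(_METRIC_GETTERS))


def _stage(name: str):
    """Tag exceptions with the pipeline stage they came from."""
    class _ctx:
        def __enter__(self):
            log.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"[{name}] {exc}") from exc
            return False
    return _ctx()


class _StageError(RuntimeError):
    pass


def quantify_kidney(source: VoxelGrid | str | Path,
                    config: dict | None = None) -> AnalysisReport:
    """Run the complete virtual-histology quantification on one volume."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(DEFAULT_CONFIG)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)

    if isinstance(source, (str, Path)):
        with _stage("read_volume"):
            grid = read_volume(source)
        src_desc = str(source)
    else:
        grid = source
        src_desc = "<in-memory grid>"

    digest = hashlib.sha256(np.ascontiguousarray(grid.values).tobytes()).hexdigest()[:16]

    with _stage("segment_organ"):
        mask = organmetrics.segment_organ(grid, cfg["organ_threshold"])
    with _stage("compute_histogram"):
        hist = histoclass.compute_histogram(grid, mask.mask, cfg["histogram_bins"])
    with _stage("fit_mixture"):
        model = histoclass.fit_mixture(hist, cfg["n_classes"])
    with _stage("envelope_inflections"):
        bounds = histoclass.envelope_inflections(hist, model, cfg["boundary_method"])
    with _stage("compartment_volumes"):
        report = histoclass.compartment_volumes(hist, bounds)
    with _stage("cortical_thickness"):
        thick = morpho.cortical_thickness(
            grid, mask, bounds, n_sites=cfg["n_thickness_sites"],
            seed=cfg["seed"], slice_axis=cfg["thickness_slice_axis"])
    with _stage("organ_surface_area"):
        area = organmetrics.organ_surface_area(mask)
    with _stage("thickness_index"):
        idx = morpho.thickness_index(area, thick.mean_thickness_mm)
    with _stage("whole_cortex_stats"):
        masks = histoclass.class_masks(grid, mask.mask, bounds)
        cortex_stats = fibrosis.whole_cortex_stats(grid, masks["cortex"])

    cube_stats = None
    try:
        with _stage("cortical_cubes"):
            cubes = fibrosis.place_cortical_cubes(
                masks["cortex"], grid.spacing_mm, cfg["cube_edge_mm"],
                cfg["n_cubes"], seed=cfg["seed"])
            cs = fibrosis.cube_grey_stats(grid, cubes)
            cube_stats = {
                "edge_mm": cfg["cube_edge_mm"],
                "centers_mm": [list(c.center_mm) for c in cubes],
                "min_gv": cs.min_gv,
                "mean_gv": cs.mean_gv,
                "max_gv": cs.max_gv,
                "aggregate_mean_gv": cs.aggregate_mean_gv,
                "aggregate_max_gv": cs.aggregate_max_gv,
            }
    except _StageError as err:
        log.warning("cube sampling skipped: %s", err)

    return AnalysisReport(
        v_kidney_mm3=report.v_kidney_mm3,
        compartments=report.to_dict(),
        cth_mm=thick.mean_thickness_mm,
        site_distances_mm=list(thick.site_distances_mm),
        a_kidney_mm2=area,
        index=idx.index,
        cortex_stats=cortex_stats,
        cube_stats=cube_stats,
        mixture={
            "components": [list(c) for c in model.components],
            "log_likelihood": model.log_likelihood,
            "converged": model.converged,
            "n_iterations": model.n_iterations,
        },
        thresholds=[float(t) for t in bounds.thresholds],
        provenance={
            "source": src_desc,
            "input_sha256_16": digest,
            "spacing_mm": grid.spacing_mm,
            "settings": cfg,
            "version": __version__,
        },
    )


_TYPE_CHECKS = {
    "number": lambda v: isinstance(v, (int, float)) and not isinstance(v, bool),
    "object": lambda v: isinstance(v, dict),
    "object_or_null": lambda v: v is None or isinstance(v, dict),
    "array": lambda v: isinstance(v, list),
}


def validate_report_dict(d: dict) -> None:
    """Check a serialized report against the checked-in schema; raise on drift."""
    import importlib.resources as res

    schema = json.loads(
        res.files("renalvh").joinpath("report_schema.json").read_text())
    for key, kind in schema["required"].items():
        if key not in d:
            raise ValueError(f"report is missing required key {key!r}")
        if not _TYPE_CHECKS[kind](d[key]):
            raise ValueError(f"report key {key!r} has wrong type")
    missing = set(schema["compartments_required"]) - set(d["compartments"])
    if missing:
        raise ValueError(f"compartments block missing keys {sorted(missing)}")


def compare_cohorts(reports_a, reports_b, metric: str,
                    group_names: tuple[str, str] = ("a", "b"),
                    equal_var: bool = True) -> fibrosis.GroupComparison:
    """Unpaired t-test on one report metric between two cohorts."""
    if len(reports_a) < 2 or len(reports_b) < 2:
        raise ValueError("need at least 2 reports per cohort")
    va = [r.metric(metric) for r in reports_a]
    vb = [r.metric(metric) for r in reports_b]
    return fibrosis.unpaired_t_test(va, vb, equal_var=equal_var,
                                    group_names=group_names)
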