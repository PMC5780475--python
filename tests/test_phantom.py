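"""Phantom generator: geometry, grey-value statistics, pathology, oracles."""

import numpy as np
import pytest

import renalvh as rv
from renalvh.phantom import AIR, CORTEX, CYST, MEDULLA, PELVIS


def small_spec(**kw):
    base = dict(voxel_spacing_mm=0.08, organ_semi_axes_mm=(2.4, 1.8, 1.5),
                seed=5)
    base.update(kw)
    return rv.PhantomSpec(**base)


class TestGeneration:
    def test_zero_noise_cortex_equals_mean_exactly(self):
        spec = small_spec(compartment_gv={"pelvis": (500.0, 0.0),
                                          "medulla": (2500.0, 0.0),
                                          "cortex": (3575.0, 0.0)},
                          noise_sd=0.0, background_gv=(100.0, 0.0))
        grid, labels = rv.generate_kidney_phantom(spec)
        assert np.all(grid.values[labels.labels == CORTEX] == 3575.0)
        assert np.all(grid.values[labels.labels == MEDULLA] == 2500.0)

    def test_cortex_fraction_matches_target(self):
        spec = small_spec(compartment_fractions=(0.12, 0.18, 0.70))
        _, labels = rv.generate_kidney_phantom(spec)
        organ = labels.labels != AIR
        frac = (labels.labels == CORTEX).sum() / organ.sum()
        assert frac == pytest.approx(0.70, abs=0.01)

    def test_determinism_under_seed(self):
        g1, l1 = rv.generate_kidney_phantom(small_spec(seed=42))
        g2, l2 = rv.generate_kidney_phantom(small_spec(seed=42))
        assert np.array_equal(g1.values, g2.values)
        assert np.array_equal(l1.labels, l2.labels)

    def test_different_seed_changes_noise(self):
        g1, _ = rv.generate_kidney_phantom(small_spec(seed=1))
        g2, _ = rv.generate_kidney_phantom(small_spec(seed=2))
        assert not np.array_equal(g1.values, g2.values)

    def test_degenerate_shell_rejected(self):
        # pelvis core thinner than one voxel
        with pytest.raises(ValueError, match="degenerate"):
            spec = small_spec(voxel_spacing_mm=0.4,
                              organ_semi_axes_mm=(2.4, 1.8, 1.5))
            rv.generate_kidney_phantom(spec)

    def test_compartment_moments_match_spec(self):
        """Per-compartment GV mean/SD within 4 standard errors of spec."""
        spec = small_spec(seed=77)
        grid, labels = rv.generate_kidney_phantom(spec)
        for lab, name in ((PELVIS, "pelvis"), (MEDULLA, "medulla"),
                          (CORTEX, "cortex")):
            vals = grid.values[labels.labels == lab]
            mu, sd = spec.compartment_gv[name]
            se = sd / np.sqrt(len(vals))
            assert vals.mean() == pytest.approx(mu, abs=4 * se)
            assert vals.std() == pytest.approx(sd, rel=0.05)

    def test_grey_value_ordering(self, healthy_phantom):
        grid, labels = healthy_phantom
        mean = {lab: grid.values[labels.labels == lab].mean()
                for lab in (PELVIS, MEDULLA, CORTEX)}
        assert mean[CORTEX] > mean[MEDULLA] > mean[PELVIS]

    def test_translation_invariance_of_truth_report(self):
        grid, labels = rv.generate_kidney_phantom(small_spec(margin_mm=0.8))
        rolled = rv.LabelGrid(np.roll(labels.labels, (3, -2, 4), axis=(0, 1, 2)),
                              labels.spacing_mm)
        a = rv.phantom_truth_report(labels).to_dict()
        b = rv.phantom_truth_report(rolled).to_dict()
        assert a == b

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            small_spec(compartment_fractions=(0.2, 0.2, 0.2))
        with pytest.raises(ValueError, match="positive"):
            small_spec(voxel_spacing_mm=-1.0)
        with pytest.raises(ValueError, match="SD"):
            small_spec(compartment_gv={"pelvis": (500, -1.0),
                                       "medulla": (2500, 1), "cortex": (3575, 1)})

    def test_spec_json_roundtrip(self, tmp_path):
        spec = small_spec(pathology=rv.PathologySpec(kind="uuo",
                                                     cortex_gv_shift=-100.0))
        p = tmp_path / "spec.json"
        spec.to_json(p)
        back = rv.PhantomSpec.from_json(p)
        assert back == spec


class TestPathology:
    def test_none_is_identity(self, healthy_phantom):
        grid, labels = healthy_phantom
        g2, l2 = rv.apply_pathology(grid, labels, None)
        assert np.array_equal(g2.values, grid.values)
        assert np.array_equal(l2.labels, labels.labels)

    def test_cyst_removes_expected_cortex_volume(self):
        spec = small_spec(seed=8)
        grid, labels = rv.generate_kidney_phantom(spec)
        # cyst centered mid-cortex along the longest axis
        center_vox = np.array(labels.shape) * spec.voxel_spacing_mm / 2.0
        s_m = spec.shell_scales[1]
        depth = spec.organ_semi_axes_mm[0] * (1 + s_m) / 2.0
        center = (center_vox[0] + depth, center_vox[1], center_vox[2])
        r = 0.25
        path = rv.PathologySpec(kind="cyst", cyst_centers_mm=[center],
                                cyst_radii_mm=[r])
        _, l2 = rv.apply_pathology(grid, labels, path, seed=1)
        lost = int((labels.labels == CORTEX).sum() - (l2.labels == CORTEX).sum())
        expected = 4.0 / 3.0 * np.pi * r ** 3 / spec.voxel_spacing_mm ** 3
        assert lost == pytest.approx(expected, rel=0.15)  # discretization
        assert np.all(l2.labels[l2.labels != labels.labels] == CYST)

    def test_cyst_outside_organ_rejected(self, healthy_phantom):
        grid, labels = healthy_phantom
        path = rv.PathologySpec(kind="cyst", cyst_centers_mm=[(0.1, 0.1, 0.1)],
                                cyst_radii_mm=[0.3])
        with pytest.raises(ValueError, match="outside the organ"):
            rv.apply_pathology(grid, labels, path)

    def test_cortex_shift_applied(self, healthy_phantom, uuo_phantom):
        grid, labels = healthy_phantom
        g2, l2 = uuo_phantom
        before = grid.values[labels.labels == CORTEX].mean()
        after = g2.values[l2.labels == CORTEX].mean()
        n = int((labels.labels == CORTEX).sum())
        se = 94.5 / np.sqrt(n)
        assert before - after == pytest.approx(536.0, abs=4 * se)

    def test_uuo_dilates_pelvis_and_extinguishes_medulla(self, healthy_phantom,
                                                         uuo_phantom):
        _, labels = healthy_phantom
        _, l2 = uuo_phantom
        t0 = rv.phantom_truth_report(labels).fractions_percent
        t1 = rv.phantom_truth_report(l2).fractions_percent
        assert t1["pelvis"] > t0["pelvis"]
        assert t1["medulla"] < 0.25 * t0["medulla"]

    def test_pathology_spec_validation(self):
        with pytest.raises(ValueError):
            rv.PathologySpec(kind="unknown")
        with pytest.raises(ValueError):
            rv.PathologySpec(kind="uuo", medulla_retention=1.5)
        with pytest.raises(ValueError):
            rv.PathologySpec(kind="uuo", pelvis_dilation_factor=0.5)


class TestTruthReport:
    def test_hand_built_counts(self):
        labels = np.zeros((10, 10, 10), dtype=np.uint8)
        flat = labels.ravel()
        flat[:300] = PELVIS
        flat[300:600] = MEDULLA
        flat[600:1000] = CORTEX
        rep = rv.phantom_truth_report(rv.LabelGrid(labels, 0.1))
        assert rep.v_pelvis_mm3 == pytest.approx(0.3)
        assert rep.v_medulla_mm3 == pytest.approx(0.3)
        assert rep.v_cortex_mm3 == pytest.approx(0.4)
        assert rep.v_kidney_mm3 == pytest.approx(1.0)

    def test_all_cortex(self):
        labels = np.full((5, 5, 5), CORTEX, dtype=np.uint8)
        rep = rv.phantom_truth_report(rv.LabelGrid(labels, 0.1))
        assert rep.fractions_percent["cortex"] == 100.0

    def test_fractions_sum_to_100(self, healthy_phantom):
        _, labels = healthy_phantom
        fr = rv.phantom_truth_report(labels).fractions_percent
        assert sum(fr.values()) == pytest.approx(100.0, abs=1e-9)
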