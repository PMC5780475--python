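"""Histogram construction, Gaussian-class EM, boundaries, volumetry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import renalvh as rv
from renalvh import (ClassBoundaries, CompartmentReport, GreyHistogram,
                     MixtureModel, VoxelGrid, compartment_volumes,
                     compute_histogram, envelope_inflections, fit_mixture)
from renalvh.phantom import AIR


def hist_from_samples(x, bins=256):
    edges = np.linspace(x.min(), x.max(), bins + 1)
    counts, _ = np.histogram(x, edges)
    return GreyHistogram(edges, counts, 1.0, len(x))


class TestHistogram:
    def test_constant_volume_single_bin(self):
        grid = VoxelGrid(np.full((4, 4, 4), 1234.0), 0.1)
        h = compute_histogram(grid)
        assert len(h.counts) == 1 and h.counts[0] == 64

    def test_two_values_equal_counts(self):
        vals = np.full((4, 4, 4), 100.0)
        vals[:2] = 900.0
        h = compute_histogram(VoxelGrid(vals, 0.1), bins="native")
        occupied = h.counts[h.counts > 0]
        assert list(occupied) == [32, 32]

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_conservation_of_masked_volume(self, seed):
        """sum(counts) * voxel volume always equals the masked volume."""
        rng = np.random.default_rng(seed)
        vals = rng.normal(1000, 200, size=(6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.4
        if not mask.any():
            mask[0, 0, 0] = True
        grid = VoxelGrid(vals, 0.05)
        h = compute_histogram(grid, mask)
        assert h.counts.sum() == mask.sum()
        assert h.masked_volume_mm3 == pytest.approx(mask.sum() * 0.05 ** 3)

    def test_empty_mask_rejected(self):
        grid = VoxelGrid(np.zeros((4, 4, 4)), 0.1)
        with pytest.raises(ValueError, match="empty mask"):
            compute_histogram(grid, np.zeros((4, 4, 4), bool))


class TestMixtureFit:
    def test_single_component_recovers_moments(self):
        rng = np.random.default_rng(3)
        x = rng.normal(3600, 120, size=200_000)
        m = fit_mixture(hist_from_samples(x), 1)
        assert m.means[0] == pytest.approx(3600, abs=2)
        assert m.sds[0] == pytest.approx(120, rel=0.02)

    def test_three_component_parameter_recovery(self):
        """EM on binned draws from a known 3-class mixture recovers it."""
        rng = np.random.default_rng(42)
        n = 10 ** 6
        comp = rng.choice(3, size=n, p=[0.15, 0.15, 0.70])
        x = rng.normal(np.take([500, 2500, 3600], comp),
                       np.take([80, 150, 120], comp))
        m = fit_mixture(hist_from_samples(x), 3)
        assert m.converged
        assert np.allclose(m.weights, [0.15, 0.15, 0.70], atol=0.01)
        assert np.allclose(m.means, [500, 2500, 3600], rtol=0.01)

    def test_agrees_with_reference_em_on_raw_samples(self):
        """Binned EM matches an independent raw-sample EM implementation."""
        from sklearn.mixture import GaussianMixture
        rng = np.random.default_rng(7)
        n = 200_000
        comp = rng.choice(3, size=n, p=[0.2, 0.3, 0.5])
        x = rng.normal(np.take([500, 2500, 3600], comp),
                       np.take([80, 150, 120], comp))
        ours = fit_mixture(hist_from_samples(x), 3)
        ref = GaussianMixture(3, random_state=0, n_init=3).fit(x[:, None])
        ref_means = np.sort(ref.means_.ravel())
        assert np.allclose(ours.means, ref_means, rtol=0.01)

    def test_stability_under_perturbed_init(self):
        rng = np.random.default_rng(5)
        comp = rng.choice(3, size=300_000, p=[0.15, 0.15, 0.70])
        x = rng.normal(np.take([500, 2500, 3600], comp),
                       np.take([80, 150, 120], comp))
        h = hist_from_samples(x)
        m1 = fit_mixture(h, 3)
        m2 = fit_mixture(h, 3, init_means=[700, 2200, 3400])
        rel = abs(m1.log_likelihood - m2.log_likelihood) / abs(m1.log_likelihood)
        assert rel < 1e-6

    def test_too_few_bins_rejected(self):
        h = GreyHistogram([0, 1, 2, 3], [5, 5, 5], 1.0, 15)
        with pytest.raises(ValueError, match="occupied bins"):
            fit_mixture(h, 3)

    def test_model_invariants_enforced(self):
        with pytest.raises(ValueError):
            MixtureModel([(0.5, 10, 1), (0.6, 20, 1)], 0, 1, True)  # weights
        with pytest.raises(ValueError):
            MixtureModel([(0.5, 20, 1), (0.5, 10, 1)], 0, 1, True)  # order


class TestBoundaries:
    def test_single_gaussian_inflections_at_mu_pm_sigma(self):
        m = MixtureModel([(1.0, 3600.0, 120.0)], 0.0, 1, True)
        assert np.allclose(m.inflection_points(), [3480.0, 3720.0])

    @pytest.mark.parametrize("method", ["fitted_envelope", "smoothed_numeric"])
    def test_symmetric_mixture_boundary_at_midpoint(self, method):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(0, 1, 500_000),
                            rng.normal(6, 1, 500_000)])
        h = hist_from_samples(x)
        m = fit_mixture(h, 2)
        b = envelope_inflections(h, m, method)
        assert b.thresholds[0] == pytest.approx(3.0, abs=0.05)
        assert b.method == method

    def test_thresholds_lie_between_adjacent_means(self, healthy_phantom):
        grid, labels = healthy_phantom
        h = compute_histogram(grid, labels.labels != AIR)
        m = fit_mixture(h, 3)
        b = envelope_inflections(h, m)
        assert m.means[0] < b.thresholds[0] < m.means[1]
        assert m.means[1] < b.thresholds[1] < m.means[2]

    def test_phantom_fractions_recovered_within_2pp(self, healthy_phantom):
        grid, labels = healthy_phantom
        organ = labels.labels != AIR
        h = compute_histogram(grid, organ)
        m = fit_mixture(h, 3)
        b = envelope_inflections(h, m)
        est = compartment_volumes(h, b).fractions_percent
        truth = rv.phantom_truth_report(labels).fractions_percent
        for k in ("pelvis", "medulla", "cortex"):
            assert est[k] == pytest.approx(truth[k], abs=2.0)

    def test_needs_two_components(self):
        m = MixtureModel([(1.0, 10.0, 1.0)], 0.0, 1, True)
        h = GreyHistogram(np.linspace(0, 20, 11), np.full(10, 10), 1.0, 100)
        with pytest.raises(ValueError, match="2 components"):
            envelope_inflections(h, m)


class TestCompartmentVolumes:
    def test_fraction_volume_conversion_worked_example(self):
        """15.57/13.5/70.93 % of a 208.7 mm³ organ are 32.5/28.2/148 mm³."""
        rep = CompartmentReport.from_fractions(208.7, (15.57, 13.5, 70.93))
        assert rep.v_pelvis_mm3 == pytest.approx(32.5, abs=0.05)
        assert rep.v_medulla_mm3 == pytest.approx(28.2, abs=0.05)
        assert rep.v_cortex_mm3 == pytest.approx(148.0, abs=0.05)

    def test_all_below_first_threshold_is_all_pelvis(self):
        counts = [25] * 4 + [0] * 36  # all mass in the lowest grey values
        h = GreyHistogram(np.linspace(0, 400, 41), counts, 1.0, 100)
        with pytest.warns(UserWarning, match="no voxels"):
            rep = compartment_volumes(h, ClassBoundaries([200.0, 300.0]))
        assert rep.fractions_percent["pelvis"] == 100.0

    def test_thresholds_outside_range_rejected(self):
        h = GreyHistogram(np.linspace(0, 100, 11), [10] * 10, 1.0, 100)
        with pytest.raises(ValueError, match="outside"):
            compartment_volumes(h, ClassBoundaries([200.0, 300.0]))

    def test_class_volumes_partition_total_exactly(self, healthy_phantom):
        grid, labels = healthy_phantom
        h = compute_histogram(grid, labels.labels != AIR)
        m = fit_mixture(h, 3)
        b = envelope_inflections(h, m)
        rep = compartment_volumes(h, b)
        parts = rep.v_pelvis_mm3 + rep.v_medulla_mm3 + rep.v_cortex_mm3
        assert parts == pytest.approx(rep.v_kidney_mm3, abs=1e-9)
        assert sum(rep.fractions_percent.values()) == pytest.approx(100.0,
                                                                    abs=0.1)

    def test_raising_cortex_threshold_never_raises_cortex_fraction(
            self, healthy_phantom):
        grid, labels = healthy_phantom
        h = compute_histogram(grid, labels.labels != AIR)
        prev = 101.0
        for thr2 in np.linspace(2800, 3400, 7):
            rep = compartment_volumes(h, ClassBoundaries([1200.0, thr2]))
            frac = rep.fractions_percent["cortex"]
            assert frac <= prev + 1e-9
            prev = frac

    def test_fraction_report_validation(self):
        with pytest.raises(ValueError, match="sum to 100"):
            CompartmentReport.from_fractions(100.0, (50.0, 30.0, 10.0))
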