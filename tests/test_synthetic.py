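"""Generator structure: composition, determinism, augmentation accounting,
and the empirical spectral signatures the simulator must reproduce."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spudnet import (
    GradeLabel,
    NoiseModel,
    SimulationConfig,
    augment_gaussian,
    make_grid,
    mean_spectrum_by_grade,
    simulate_dataset,
    simulate_spectrum,
)
from spudnet.synthetic import GRADES, SpectralDataset, WavelengthGrid


class TestGrid:
    def test_endpoints_only(self):
        assert np.allclose(make_grid(2, 350, 1000).values, [350, 1000])

    def test_midpoint(self):
        assert np.allclose(make_grid(3, 400, 800).values, [400, 600, 800])

    def test_default_resolution_step(self):
        g = make_grid(2048, 350, 1000)
        assert np.allclose(np.diff(g.values), (1000 - 350) / 2047)

    @pytest.mark.parametrize("args", [(1, 350, 1000), (3, 300, 900), (3, 900, 1100), (3, 700, 600)])
    def test_rejects_out_of_range(self, args):
        with pytest.raises(ValueError):
            make_grid(*args)

    def test_grid_must_increase(self):
        with pytest.raises(ValueError):
            WavelengthGrid(np.array([400.0, 400.0, 500.0]))


class TestSimulate:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_points=128)
        a = simulate_spectrum(GradeLabel.GRADE3, cfg, seed=7)
        b = simulate_spectrum(GradeLabel.GRADE3, cfg, seed=7)
        assert np.array_equal(a.intensities, b.intensities)
        c = simulate_spectrum(GradeLabel.GRADE3, cfg, seed=8)
        assert not np.array_equal(a.intensities, c.intensities)

    def test_intensities_finite_nonnegative(self):
        cfg = SimulationConfig(n_points=256)
        for g in GRADES:
            s = simulate_spectrum(g, cfg, seed=3)
            assert np.all(np.isfinite(s.intensities))
            assert np.all(s.intensities >= 0)

    def test_default_composition_and_total(self):
        ds = simulate_dataset(SimulationConfig(n_points=16))
        assert len(ds) == 643
        assert ds.composition == {
            GradeLabel.HEALTHY: 265,
            GradeLabel.GRADE2: 150,
            GradeLabel.GRADE3: 78,
            GradeLabel.GRADE4: 150,
        }
        assert len(set(ds.tuber_ids)) == 643
        assert np.all(ds.replicate_index == 0)

    def test_single_spectrum_dataset(self):
        ds = simulate_dataset(SimulationConfig(n_points=16, composition=(1, 0, 0, 0)))
        assert len(ds) == 1
        assert ds.grades[0] == GradeLabel.HEALTHY


@pytest.fixture(scope="module")
def structural_dataset():
    # >=100 tubers per grade on a fine grid for mean-curve geometry checks
    cfg = SimulationConfig(n_points=1024, composition=(200, 200, 200, 200), seed=0)
    return cfg, simulate_dataset(cfg)


class TestSpectralStructure:
    def test_healthy_above_severe_in_500_850(self, structural_dataset):
        cfg, ds = structural_dataset
        means = mean_spectrum_by_grade(ds)
        lam = cfg.grid.values
        band = (lam >= 500) & (lam <= 850)
        assert np.mean(means[GradeLabel.HEALTHY][band]) > np.mean(
            means[GradeLabel.GRADE4][band]
        )

    def test_severity_ordering_pointwise_650_850(self, structural_dataset):
        cfg, ds = structural_dataset
        means = mean_spectrum_by_grade(ds)
        lam = cfg.grid.values
        band = (lam >= 650) & (lam <= 850)
        curves = [means[g][band] for g in GRADES]
        for upper, lower in zip(curves, curves[1:]):
            assert np.all(upper > lower)

    def test_grade2_coincides_with_healthy_in_500_650(self, structural_dataset):
        cfg, ds = structural_dataset
        means = mean_spectrum_by_grade(ds)
        lam = cfg.grid.values
        band = (lam >= 500) & (lam <= 650)
        h = means[GradeLabel.HEALTHY][band]
        rel2 = np.abs(means[GradeLabel.GRADE2][band] - h) / h
        assert rel2.max() < 0.02
        for g in (GradeLabel.GRADE3, GradeLabel.GRADE4):
            rel = np.abs(means[g][band] - h) / h
            assert rel.max() > 0.05

    def test_difference_curve_peaks_near_703(self, structural_dataset):
        cfg, ds = structural_dataset
        means = mean_spectrum_by_grade(ds)
        diff = means[GradeLabel.HEALTHY] - means[GradeLabel.GRADE4]
        peak = cfg.grid.values[np.argmax(diff)]
        assert 693 <= peak <= 713


class TestAugmentation:
    def test_study_scale_expansion(self):
        ds = simulate_dataset(SimulationConfig(n_points=8))
        out = augment_gaussian(ds, NoiseModel(replicates_per_original=5, seed=0))
        assert len(out) == 3858

    def test_zero_replicates_identity(self, smoke_dataset):
        out = augment_gaussian(smoke_dataset, NoiseModel(replicates_per_original=0))
        assert len(out) == len(smoke_dataset)
        assert np.array_equal(out.intensities, smoke_dataset.intensities)

    def test_replicates_carry_parent_identity(self):
        ds = simulate_dataset(SimulationConfig(n_points=8, composition=(4, 2, 3, 1)))
        out = augment_gaussian(ds, NoiseModel(replicates_per_original=3, seed=1))
        assert len(out) == 40
        assert int((out.replicate_index >= 1).sum()) == 30
        originals = {str(t) for t in ds.tuber_ids}
        assert {str(t) for t in out.tuber_ids} == originals

    def test_deterministic_given_seed(self, smoke_dataset):
        a = augment_gaussian(smoke_dataset, NoiseModel(seed=3))
        b = augment_gaussian(smoke_dataset, NoiseModel(seed=3))
        assert np.array_equal(a.intensities, b.intensities)

    @given(n=st.integers(1, 6), m=st.integers(0, 4))
    @settings(max_examples=15, deadline=None)
    def test_counting_invariant(self, n, m):
        ds = simulate_dataset(SimulationConfig(n_points=8, composition=(n, 0, 0, 0)))
        out = augment_gaussian(ds, NoiseModel(replicates_per_original=m, seed=0))
        assert len(out) == n * (1 + m)

    def test_negative_replicates_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(replicates_per_original=-1)


class TestMeanSpectra:
    def test_single_spectrum_is_its_own_mean(self):
        ds = simulate_dataset(SimulationConfig(n_points=16, composition=(1, 0, 0, 0)))
        means = mean_spectrum_by_grade(ds)
        assert np.allclose(means[GradeLabel.HEALTHY], ds.intensities[0])

    def test_duplicates_average_to_themselves(self):
        ds = simulate_dataset(SimulationConfig(n_points=16, composition=(1, 0, 0, 0)))
        dup = SpectralDataset(
            grid=ds.grid,
            intensities=np.vstack([ds.intensities, ds.intensities]),
            grades=np.tile(ds.grades, 2),
            tuber_ids=np.tile(ds.tuber_ids, 2),
            replicate_index=np.array([0, 1]),
        )
        assert np.allclose(
            mean_spectrum_by_grade(dup)[GradeLabel.HEALTHY], ds.intensities[0]
        )

    def test_empty_dataset_rejected(self):
        ds = simulate_dataset(SimulationConfig(n_points=16, composition=(1, 0, 0, 0)))
        with pytest.raises(ValueError):
            mean_spectrum_by_grade(ds.subset([]))
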