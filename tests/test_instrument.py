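"""Synthetic-instrument forward model: resolution, noise, scenarios,
trajectories."""

import numpy as np
import pytest

from qensmem.instrument import (
    DEFAULT_Q_SET,
    ResolutionKernel,
    convolve,
    generate_background,
    generate_dataset,
    generate_spectrum,
    generate_trajectories,
    make_resolution,
    sphere_eisf,
)
from qensmem.models import (
    Delta,
    EnergyGrid,
    Gaussian,
    Lorentzian,
    ModelTermSet,
)


class TestResolutionKernel:
    def test_gaussian_sd_from_fwhm(self, kernel):
        assert kernel.gaussian_sd == pytest.approx(0.75 / 2.3548, abs=1e-4)

    def test_unit_area(self, kernel):
        assert kernel.values.sum() * kernel.grid.bin_width == pytest.approx(
            1.0, abs=1e-9
        )

    def test_symmetry(self, kernel):
        np.testing.assert_allclose(kernel.values, kernel.values[::-1], atol=1e-12)

    def test_narrow_grid_rejected(self):
        with pytest.raises(ValueError):
            make_resolution(EnergyGrid.symmetric(3.0, 0.1), fwhm=0.75)


class TestGenerateSpectrum:
    def test_resolution_limited_elastic_line(self, kernel):
        """A purely elastic scatterer must show the instrument line width."""
        model = ModelTermSet(terms=((1.0, Delta()),))
        spec = generate_spectrum(model, kernel, 10**6, rng=0)
        half = spec.intensity.max() / 2.0
        above = spec.grid.omega[spec.intensity > half]
        fwhm = above[-1] - above[0]
        assert abs(fwhm - 0.75) <= 2 * spec.grid.bin_width

    def test_seed_reproducibility(self, kernel):
        model = ModelTermSet(terms=((1.0, Lorentzian(0.5)),))
        a = generate_spectrum(model, kernel, 10**5, rng=7)
        b = generate_spectrum(model, kernel, 10**5, rng=7)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_poisson_mean_matches_expectation(self):
        """Replicate means must match the noiseless expectation bin-wise."""
        grid = EnergyGrid.symmetric(8.0, 0.1)
        kern = make_resolution(grid, 0.75)
        model = ModelTermSet(terms=((1.0, Lorentzian(0.5)),), flat_background=0.01)
        total = 200_000
        expected = convolve(model, kern) * grid.bin_width
        expected *= total / expected.sum()
        rng = np.random.default_rng(42)
        reps = np.stack(
            [generate_spectrum(model, kern, total, rng).intensity for _ in range(200)]
        )
        se = np.sqrt(expected / 200)
        frac_ok = np.mean(np.abs(reps.mean(axis=0) - expected) <= 3 * se)
        assert frac_ok >= 0.99


class TestConvolve:
    def _model(self):
        return ModelTermSet(
            terms=((0.5, Delta()), (0.3, Lorentzian(0.4)), (0.2, Gaussian(1.5))),
            flat_background=0.002,
        )

    def test_analytic_matches_numeric_path(self, kernel, tabulated_kernel):
        analytic = convolve(self._model(), kernel)
        numeric = convolve(self._model(), tabulated_kernel)
        assert np.max(np.abs(analytic - numeric)) / analytic.max() < 1e-4

    def test_numeric_convolution_conserves_intensity(self, tabulated_kernel):
        """Convolution must not change the grid sum (localized model)."""
        model = ModelTermSet(terms=((1.0, Gaussian(1.0)),), flat_background=0.0)
        before = model.evaluate(tabulated_kernel.grid.omega).sum()
        after = convolve(model, tabulated_kernel).sum()
        assert after == pytest.approx(before, rel=1e-6)

    def test_delta_maps_to_kernel(self, kernel):
        model = ModelTermSet(terms=((2.0, Delta()),))
        out = convolve(model, kernel)
        peak = out.max() * kernel.grid.bin_width
        # Gaussian of sd 0.3185: peak density * 2 weight
        assert peak == pytest.approx(
            2.0 * kernel.grid.bin_width / (kernel.gaussian_sd * np.sqrt(2 * np.pi)),
            rel=1e-3,
        )


class TestGenerateDataset:
    def test_generating_widths_follow_dispersion(self):
        data = generate_dataset(
            "pure_lipid", "diffusion", D_lipid=21e-8, counts=1000, seed=0
        )
        per_q = {t["Q"]: t for t in data.truth["per_Q"]}
        assert per_q[0.29]["lipid_width"] == pytest.approx(0.1163, abs=2e-4)
        assert [s.Q for s in data.spectra] == list(DEFAULT_Q_SET)

    def test_peptide_width_sub_resolution(self):
        data = generate_dataset(
            "lipid_peptide",
            "diffusion",
            D_peptide=0.5e-8,
            p=0.2,
            counts=1000,
            seed=0,
        )
        per_q = {t["Q"]: t for t in data.truth["per_Q"]}
        assert per_q[0.95]["peptide_width"] == pytest.approx(0.0297, abs=1e-4)

    def test_sphere_eisf_limits(self):
        assert sphere_eisf(0.0) == pytest.approx(1.0)
        assert sphere_eisf(1e-9) == pytest.approx(1.0, abs=1e-6)
        assert 0.0 < sphere_eisf(0.95) < sphere_eisf(0.29) < 1.0

    def test_out_of_range_Q_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(
                "pure_lipid", "diffusion", Q_set=[0.01], counts=1000, seed=0
            )

    def test_extended_scenario_truth(self):
        data = generate_dataset(
            "extended",
            "diffusion",
            D_lipid=8e-8,
            D_free=21e-8,
            influenced_fraction=0.8,
            counts=1000,
            seed=0,
        )
        t = data.truth["per_Q"][0]
        assert t["width_1"] > t["width_2"]
        assert t["l"] == pytest.approx(0.2)


class TestBackgroundAndTrajectories:
    def test_zero_level_background(self, kernel):
        spec = generate_background(0.0, kernel, rng=0)
        assert spec.intensity.sum() == 0.0

    def test_background_mean_scales_with_level(self, kernel):
        means = []
        for level in (50.0, 100.0):
            spec = generate_background(level, kernel, rng=3)
            means.append(spec.intensity.mean())
        assert means[1] / means[0] == pytest.approx(2.0, rel=0.05)

    def test_frozen_trajectories_at_zero_D(self):
        traj = generate_trajectories(0.0, n_mol=5, dt=0.1, t_max=1.0, seed=0)
        assert np.all(traj.positions == traj.positions[:, :1, :])

    def test_einstein_relation(self):
        """Ensemble MSD at lag t must match 4 D t."""
        D = 2.1  # A^2/ns in cm^2/s units: 2.1e-7
        traj = generate_trajectories(2.1e-7, n_mol=500, dt=0.1, t_max=10.0, seed=1)
        lag_frames = 50  # 5 ns
        disp = traj.positions[:, lag_frames, :] - traj.positions[:, 0, :]
        msd = np.mean(np.sum(disp**2, axis=-1))
        expected = 4.0 * D * 5.0
        se = np.std(np.sum(disp**2, axis=-1)) / np.sqrt(500)
        assert abs(msd - expected) <= 3 * se

    def test_trajectory_seed_reproducibility(self):
        a = generate_trajectories(1e-7, 10, 0.1, 1.0, seed=5)
        b = generate_trajectories(1e-7, 10, 0.1, 1.0, seed=5)
        np.testing.assert_array_equal(a.positions, b.positions)
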