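"""Adaptive Metropolis sampler, chi-squared statistics and model ranking."""

import numpy as np
import pytest
from scipy import stats

from qensmem.fitting import (
    Chi2Pdf,
    DirectProblem,
    Param,
    SpectraFitProblem,
    chi2_pdf,
    chi_squared,
    compare_models,
    refine_start,
    run_mcmc,
)
from qensmem.instrument import (
    Spectrum,
    convolve,
    generate_spectrum,
    make_resolution,
)
from qensmem.models import EnergyGrid, Lorentzian, ModelTermSet


def _single_lorentzian_problem(gamma=0.5, counts=500_000, seed=0, noiseless=False):
    """One spectrum, three free parameters (amplitude, HWHM, background)."""
    grid = EnergyGrid.symmetric(15.0, 0.1)
    kern = make_resolution(grid, 0.75)
    model = ModelTermSet(terms=((1.0, Lorentzian(gamma)),), flat_background=0.002)
    if noiseless:
        expected = convolve(model, kern) * grid.bin_width
        expected *= counts / expected.sum()
        spec = Spectrum(
            Q=0.5,
            grid=grid,
            intensity=expected,
            uncertainty=np.sqrt(np.maximum(expected, 1.0)),
        )
        scale = counts / (1.0 + 0.002 * grid.n_bins * grid.bin_width)
    else:
        spec = generate_spectrum(model, kern, counts, rng=seed, Q=0.5)
        scale = counts / (1.0 + 0.002 * grid.n_bins * grid.bin_width)
    params = [
        Param("a", scale, 0.0, 10.0 * counts, 0.005 * counts, q_index=0),
        Param("gamma", gamma if noiseless else 0.3, 1e-4, 10.0, 0.05, q_index=0),
        Param("c", 0.002 * scale * 0.1, 0.0, counts / 10.0, 1.0, q_index=0),
    ]
    bw = grid.bin_width

    def expected_fn(q, theta):
        m = ModelTermSet(terms=((theta[0], Lorentzian(theta[1])),))
        return convolve(m, kern) * bw + theta[2]

    return SpectraFitProblem([spec], kern, params, expected_fn), gamma


class TestChiSquared:
    def test_perfect_model_gives_zero(self, grid):
        spec = Spectrum(
            Q=0.3,
            grid=grid,
            intensity=np.full(grid.n_bins, 5.0),
            uncertainty=np.ones(grid.n_bins),
        )
        assert chi_squared([spec], [spec.intensity]) == 0.0

    def test_one_sigma_deviation_counts_one(self, grid):
        intensity = np.full(grid.n_bins, 5.0)
        spec = Spectrum(
            Q=0.3, grid=grid, intensity=intensity, uncertainty=np.full(grid.n_bins, 2.0)
        )
        model = intensity.copy()
        model[10] += 2.0  # exactly one sigma
        assert chi_squared([spec], [model]) == pytest.approx(1.0)

    def test_zero_uncertainty_rejected(self, grid):
        spec = Spectrum(
            Q=0.3,
            grid=grid,
            intensity=np.ones(grid.n_bins),
            uncertainty=np.zeros(grid.n_bins),
        )
        with pytest.raises(ValueError):
            chi_squared([spec], [spec.intensity])

    def test_reduced_chi2_near_one_for_poisson_data(self):
        """chi2/dof ~ 1 when the model is the generating truth (>= 1e4 bins)."""
        grid = EnergyGrid.symmetric(30.0, 0.1)
        kern = make_resolution(grid, 0.75)
        model = ModelTermSet(terms=((1.0, Lorentzian(0.8)),), flat_background=0.005)
        rng = np.random.default_rng(3)
        chi2, n = 0.0, 0
        for _ in range(20):
            total = 300_000
            expected = convolve(model, kern) * grid.bin_width
            expected *= total / expected.sum()
            spec = generate_spectrum(model, kern, total, rng=rng)
            chi2 += chi_squared([spec], [expected])
            n += grid.n_bins
        assert 0.9 <= chi2 / n <= 1.1


class TestSampler:
    def test_recovers_known_hwhm(self):
        problem, gamma = _single_lorentzian_problem(seed=1)
        refine_start(problem)
        chain = run_mcmc(problem, cycles=30_000, adapt_every=3_000, seed=1)
        mean, sd = chain.mean("gamma"), chain.std("gamma")
        assert abs(mean - gamma) <= 3 * max(sd, 1e-4)

    def test_noiseless_data_reach_tiny_chi2(self):
        problem, _ = _single_lorentzian_problem(noiseless=True)
        chain = run_mcmc(problem, cycles=5_000, adapt_every=1_000, seed=0)
        _, best = chain.best()
        dof = 301 - 3
        assert best / dof < 1e-3

    def test_seed_determinism(self):
        problem1, _ = _single_lorentzian_problem(seed=2)
        problem2, _ = _single_lorentzian_problem(seed=2)
        c1 = run_mcmc(problem1, cycles=5_000, adapt_every=1_000, seed=9)
        c2 = run_mcmc(problem2, cycles=5_000, adapt_every=1_000, seed=9)
        np.testing.assert_array_equal(c1.samples, c2.samples)
        np.testing.assert_array_equal(c1.chi2_trace, c2.chi2_trace)

    def test_acceptance_rate_near_target_after_adaptation(self):
        problem, _ = _single_lorentzian_problem(seed=4)
        refine_start(problem)
        chain = run_mcmc(problem, cycles=50_000, adapt_every=5_000, seed=4)
        assert 0.66 - 0.15 <= chain.acceptance_rate <= 0.66 + 0.15

    def test_stuck_chain_raises_diagnostic(self):
        params = [Param("x", 0.5, 0.5, 0.5 + 1e-15, 1.0)]
        problem = DirectProblem(params, lambda th: 0.0)
        with pytest.raises(RuntimeError):
            run_mcmc(problem, cycles=2_000, adapt_every=1_000, seed=0)

    def test_detailed_balance_against_enumeration(self):
        """With adaptation frozen, the sampler's occupancy on a 1D posterior
        must match direct quadrature of exp(-chi2/2) to < 2% total variation."""

        def chi2_fn(theta):
            x = theta[0]
            return ((x - 0.4) / 0.15) ** 2 + 2.0 * np.cos(8.0 * x)

        params = [Param("x", 0.5, 0.0, 1.0, 0.25)]
        problem = DirectProblem(params, chi2_fn)
        cycles = 400_000
        chain = run_mcmc(
            problem, cycles=cycles, adapt_every=cycles, seed=8, burn_in=5_000
        )
        xs = chain.samples[:, 0]
        edges = np.linspace(0.0, 1.0, 21)
        occ, _ = np.histogram(xs, bins=edges)
        occ = occ / occ.sum()
        fine = np.linspace(0.0, 1.0, 20_001)
        dens = np.exp(-0.5 * np.array([chi2_fn([x]) for x in fine]))
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]))])
        cdf /= cdf[-1]
        target = np.diff(np.interp(edges, fine, cdf))
        tv = 0.5 * np.sum(np.abs(occ - target))
        assert tv < 0.02

    def test_chi2_distribution_matches_shifted_chi2_law(self):
        """Linear-Gaussian toy posterior: delta-chi2 over the minimum follows
        a chi-squared law with dof = number of free parameters."""
        rng = np.random.default_rng(17)
        x = np.linspace(0.0, 1.0, 50)
        sigma = 0.1
        y = 1.3 * x + 0.2 + rng.normal(0.0, sigma, x.size)

        def chi2_fn(theta):
            return float(np.sum((y - theta[0] * x - theta[1]) ** 2)) / sigma**2

        # analytic minimum from ordinary least squares
        slope, intercept = np.polyfit(x, y, 1)
        chi2_min = chi2_fn([slope, intercept])
        params = [
            Param("m", slope, -10.0, 10.0, 0.05),
            Param("b", intercept, -10.0, 10.0, 0.02),
        ]
        problem = DirectProblem(params, chi2_fn)
        chain = run_mcmc(
            problem, cycles=300_000, adapt_every=30_000, seed=17, burn_in=30_000
        )
        delta = chain.chi2_trace[::25] - chi2_min
        ks = stats.kstest(delta, stats.chi2(df=2).cdf).statistic
        assert ks < 0.05


class TestGlobalTransportOption:
    def test_global_D_agrees_with_dispersion_route(self):
        """The optional global-D parametrization must recover the generating
        diffusion coefficient directly (transport parameter in A^2/ns)."""
        from qensmem.fitting import lipid_fit_problem
        from qensmem.instrument import generate_dataset

        data = generate_dataset(
            "pure_lipid", "diffusion", D_lipid=21e-8, counts=300_000, seed=13
        )
        problem = lipid_fit_problem(
            data.spectra, data.kernel, "diffusion", global_transport=True
        )
        refine_start(problem)
        chain = run_mcmc(problem, cycles=20_000, adapt_every=2_000, seed=13)
        D_cm2 = chain.mean("transport") / 1e7
        assert D_cm2 == pytest.approx(21e-8, rel=0.1)


class TestChi2PdfAndComparison:
    def test_constant_chain_single_bin(self):
        chain = run_mcmc(
            DirectProblem([Param("x", 0.5, 0.0, 1.0, 0.1)], lambda th: 7.0),
            cycles=2_000,
            adapt_every=1_000,
            seed=0,
        )
        pdf = chi2_pdf(chain, n_bins=10)
        assert np.count_nonzero(pdf.density) == 1
        assert pdf.area == pytest.approx(1.0)

    def test_pdf_area_is_one(self):
        problem, _ = _single_lorentzian_problem(seed=6)
        chain = run_mcmc(problem, cycles=10_000, adapt_every=1_000, seed=6)
        assert chi2_pdf(chain).area == pytest.approx(1.0, rel=1e-9)

    def test_identical_pdfs_inconclusive(self):
        edges = np.linspace(10.0, 20.0, 11)
        density = np.full(10, 0.1)
        pdf = Chi2Pdf(edges=edges, density=density)
        assert compare_models(pdf, pdf).preferred == "inconclusive"

    def test_shifted_pdf_prefers_smaller_chi2(self):
        edges = np.linspace(10.0, 20.0, 11)
        density = stats.norm(15.0, 2.0).pdf(0.5 * (edges[:-1] + edges[1:]))
        density /= np.sum(density * np.diff(edges))
        pdf_a = Chi2Pdf(edges=edges, density=density)
        pdf_b = Chi2Pdf(edges=edges + 10.0, density=density)
        assert compare_models(pdf_a, pdf_b).preferred == "a"
        assert compare_models(pdf_b, pdf_a).preferred == "b"
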