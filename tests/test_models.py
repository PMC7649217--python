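"""Line shapes, model builders and dispersion-relation conversions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qensmem.models import (
    D_from_gamma,
    Delta,
    EnergyGrid,
    ExtendedLipidParams,
    Gaussian,
    LipidParams,
    Lorentzian,
    ModelTermSet,
    PeptideParams,
    Voigt,
    build_extended_model,
    build_lipid_model,
    build_membrane_model,
    gamma_from_D,
    gaussian,
    lorentzian,
    sigma_from_v0,
    v0_from_sigma,
)


class TestElementaryShapes:
    @pytest.mark.parametrize(
        "hwhm, omega, expected",
        [
            (1.0, 0.0, 1.0 / np.pi),  # peak of unit Lorentzian
            (1.0, 1.0, 1.0 / (2.0 * np.pi)),  # half maximum at the HWHM
        ],
    )
    def test_lorentzian_values(self, hwhm, omega, expected):
        assert lorentzian(hwhm, omega) == pytest.approx(expected, rel=1e-12)

    def test_lorentzian_unit_area(self):
        om = np.linspace(-1e4, 1e4, 4_000_001)
        assert np.trapezoid(lorentzian(0.5, om), om) == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize(
        "sd, omega, expected",
        [
            (1.0, 0.0, 1.0 / np.sqrt(2 * np.pi)),
            (2.0, 2.0, np.exp(-0.5) / (2 * np.sqrt(2 * np.pi))),
        ],
    )
    def test_gaussian_values(self, sd, omega, expected):
        assert gaussian(sd, omega) == pytest.approx(expected, rel=1e-12)

    def test_gaussian_unit_area(self):
        om = np.linspace(-8, 8, 200_001)
        assert np.trapezoid(gaussian(1.0, om), om) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_widths_rejected(self, bad):
        with pytest.raises(ValueError):
            lorentzian(bad, 0.0)
        with pytest.raises(ValueError):
            gaussian(bad, 0.0)


class TestModelBuilders:
    def test_eisf_one_removes_local_broadening(self):
        params = LipidParams(A_s=1.0, Gamma_s=2.0, long_range=0.3, a=2.0)
        model = build_lipid_model(params, "diffusion", background=0.1)
        assert len(model.terms) == 1
        (w, shape), = model.terms
        assert w == pytest.approx(2.0)
        assert isinstance(shape, Lorentzian) and shape.hwhm == pytest.approx(0.3)
        assert model.flat_background == pytest.approx(0.1)

    def test_diffusion_mode_width_addition(self):
        params = LipidParams(A_s=0.5, Gamma_s=2.0, long_range=0.3, a=1.0)
        model = build_lipid_model(params, "diffusion")
        hwhms = sorted(s.hwhm for _, s in model.terms)
        weights = sorted(w for w, _ in model.terms)
        assert hwhms == pytest.approx([0.3, 2.3])
        assert weights == pytest.approx([0.5, 0.5])

    def test_flow_mode_matches_discrete_convolution_oracle(self):
        """The analytic Voigt expansion of G(sigma) (x) [A_s d + (1-A_s) L]
        must agree with brute-force discrete convolution."""
        A_s, gamma_s, sigma = 0.6, 2.0, 0.8
        params = LipidParams(A_s=A_s, Gamma_s=gamma_s, long_range=sigma, a=1.0)
        model = build_lipid_model(params, "flow")
        dw = 0.005
        om = np.arange(-40.0, 40.0 + dw / 2, dw)
        analytic = model.evaluate(om)
        # direct-summation oracle on a widely padded grid
        om_ext = np.arange(-80.0, 80.0 + dw / 2, dw)
        g = gaussian(sigma, om_ext)
        local = A_s * g + (1.0 - A_s) * np.convolve(
            lorentzian(gamma_s, om_ext), g, mode="same"
        ) * dw
        i0 = np.searchsorted(om_ext, om[0] - dw / 2)
        oracle = local[i0 : i0 + om.size]
        assert np.max(np.abs(analytic - oracle)) / analytic.max() < 1e-4

    def test_membrane_limits(self):
        lipid = LipidParams(A_s=0.5, Gamma_s=2.0, long_range=0.3, a=1.3)
        om = np.linspace(-30, 30, 601)
        pure = build_lipid_model(lipid, "diffusion", background=0.01).evaluate(om)
        pep0 = PeptideParams(B_s=0.7, Gamma_s_peptide=3.0, Gamma_peptide=0.05, b=1.0, p=0.0)
        combined = build_membrane_model(lipid, pep0, "diffusion", background=0.01)
        np.testing.assert_allclose(combined.evaluate(om), pure, rtol=1e-12)

        pep1 = PeptideParams(B_s=0.7, Gamma_s_peptide=3.0, Gamma_peptide=0.05, b=2.0, p=1.0)
        only_pep = build_membrane_model(lipid, pep1, "diffusion")
        hwhms = sorted(s.hwhm for w, s in only_pep.terms if w > 0)
        assert hwhms == pytest.approx([0.05, 3.05])

    def test_membrane_additivity(self):
        lipid = LipidParams(A_s=0.4, Gamma_s=4.0, long_range=0.5, a=1.1)
        pep = PeptideParams(B_s=0.8, Gamma_s_peptide=5.0, Gamma_peptide=0.03, b=0.9, p=0.3)
        om = np.linspace(-30, 30, 601)
        combined = build_membrane_model(lipid, pep, "flow", background=0.002)
        lip_only = build_lipid_model(
            LipidParams(A_s=0.4, Gamma_s=4.0, long_range=0.5, a=0.7 * 1.1), "flow"
        )
        pep_only = build_membrane_model(
            LipidParams(A_s=0.4, Gamma_s=4.0, long_range=0.5, a=0.0),
            pep,
            "flow",
        )
        np.testing.assert_allclose(
            combined.evaluate(om),
            lip_only.evaluate(om) + pep_only.evaluate(om) + 0.002,
            rtol=1e-12,
            atol=1e-15,
        )

    @pytest.mark.parametrize("l, width_1, width_2", [(1.0, 0.4, 0.1), (0.0, 0.4, 0.1), (0.5, 0.3, 0.3)])
    def test_extended_degenerate_limits(self, l, width_1, width_2):
        lipid = LipidParams(A_s=0.6, Gamma_s=3.0, long_range=0.4, a=1.0)
        pep = PeptideParams(B_s=0.7, Gamma_s_peptide=4.0, Gamma_peptide=0.04, b=1.0, p=0.2)
        ext = ExtendedLipidParams(l=l, width_1=width_1, width_2=width_2)
        om = np.linspace(-30, 30, 601)
        extended = build_extended_model(lipid, pep, ext, "diffusion").evaluate(om)
        effective = width_1 if l == 1.0 else width_2
        single = build_membrane_model(
            LipidParams(A_s=0.6, Gamma_s=3.0, long_range=effective, a=1.0),
            pep,
            "diffusion",
        ).evaluate(om)
        np.testing.assert_allclose(extended, single, rtol=1e-12, atol=1e-15)


class TestTermSetProperties:
    def _sample_model(self):
        lipid = LipidParams(A_s=0.55, Gamma_s=3.5, long_range=0.45, a=1.2)
        pep = PeptideParams(B_s=0.8, Gamma_s_peptide=5.0, Gamma_peptide=0.05, b=0.8, p=0.25)
        return build_membrane_model(lipid, pep, "flow", background=0.001)

    def test_nonnegative_and_symmetric(self, grid):
        vals = self._sample_model().evaluate(grid.omega)
        assert np.all(vals >= 0)
        np.testing.assert_allclose(vals, vals[::-1], rtol=1e-10)

    def test_integrated_intensity_equals_weight_sum(self):
        model = self._sample_model()
        om = np.linspace(-4000, 4000, 1_600_001)
        area = np.trapezoid(model.evaluate(om) - model.flat_background, om)
        assert area == pytest.approx(model.total_weight, rel=2e-3)

    @given(
        g1=st.floats(0.05, 5.0),
        g2=st.floats(0.05, 5.0),
    )
    @settings(max_examples=20, deadline=None)
    def test_lorentzian_convolution_adds_widths(self, g1, g2):
        """L(g1) (x) L(g2) = L(g1+g2), checked against numerical convolution
        on a grid extending >= 40 HWHM."""
        dw = (g1 + g2) / 40.0
        half = 40.0 * (g1 + g2)
        om = np.arange(-half, half + dw / 2, dw)
        conv = np.convolve(lorentzian(g1, om), lorentzian(g2, om), mode="same") * dw
        analytic = lorentzian(g1 + g2, om)
        keep = np.abs(om) < half / 2  # away from truncation edges
        err = np.max(np.abs(conv[keep] - analytic[keep])) / analytic.max()
        assert err < 1e-3


class TestDispersionRelations:
    @pytest.mark.parametrize(
        "Q, D, expected",
        [
            (0.95, 21e-8, 1.2475),
            (0.0, 5e-8, 0.0),
            (0.95, 0.5e-8, 0.0297),
        ],
    )
    def test_gamma_from_D(self, Q, D, expected):
        assert gamma_from_D(Q, D) == pytest.approx(expected, abs=2e-4)

    @pytest.mark.parametrize(
        "Q, v0, expected", [(0.57, 0.27, 1.0130), (0.0, 0.3, 0.0)]
    )
    def test_sigma_from_v0(self, Q, v0, expected):
        assert sigma_from_v0(Q, v0) == pytest.approx(expected, abs=2e-4)

    def test_round_trips(self):
        assert v0_from_sigma(0.57, sigma_from_v0(0.57, 0.27)) == pytest.approx(
            0.27, rel=1e-12
        )
        assert D_from_gamma(0.78, gamma_from_D(0.78, 8e-8)) == pytest.approx(
            8e-8, rel=1e-12
        )

    @given(Q=st.floats(0.05, 2.0), D=st.floats(1e-9, 1e-6))
    @settings(max_examples=50, deadline=None)
    def test_gamma_linear_in_D_quadratic_in_Q(self, Q, D):
        assert gamma_from_D(Q, 2 * D) == pytest.approx(2 * gamma_from_D(Q, D), rel=1e-12)
        assert gamma_from_D(2 * Q, D) == pytest.approx(4 * gamma_from_D(Q, D), rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            gamma_from_D(-0.1, 1e-8)
        with pytest.raises(ValueError):
            sigma_from_v0(0.3, -1.0)


class TestEnergyGrid:
    def test_symmetric_grid(self):
        g = EnergyGrid.symmetric(30.0, 0.1)
        assert g.n_bins == 601
        assert g.bin_width == pytest.approx(0.1)
        assert g.omega[300] == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "omega",
        [
            np.array([0.0, 0.1, 0.15]),  # not equidistant
            np.array([1.0, 2.0, 3.0]),  # does not bracket zero
            np.array([0.2, 0.1, 0.0, -0.1]),  # not increasing
        ],
    )
    def test_invalid_grids_rejected(self, omega):
        with pytest.raises(ValueError):
            EnergyGrid(omega)

    def test_delta_cannot_be_discretized(self):
        model = ModelTermSet(terms=((1.0, Delta()),))
        with pytest.raises(ValueError):
            model.evaluate(np.linspace(-1, 1, 21))
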