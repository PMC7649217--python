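"""Analytic line shapes and composite QENS scattering models.

The measured dynamic structure factor of a lipid membrane near the elastic line
is modelled as a long-range translational term (Lorentzian for continuous
diffusion, Gaussian for flow-like ballistic motion) convolved with a localized
slow motion (elastic fraction ``A_s`` plus a Lorentzian of HWHM ``Gamma_s``),
on top of a flat background that absorbs motions too fast for the energy
window.  Peptide-loaded membranes add a second, spectrally weighted component
of the same structure, and the two-population extension splits the lipid term
into a free and a slowed fraction.

All model algebra is carried out symbolically on weighted term sets:
Lorentzian x Lorentzian convolutions add HWHMs, Gaussian x Gaussian add
variances, and Gaussian x Lorentzian is an exact Voigt profile.  Delta
components are never discretized; they only acquire a shape on convolution
with the instrument resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Union

import numpy as np
from scipy.special import voigt_profile

from .constants import CM2_PER_S_TO_A2_PER_NS, HBAR_UEV_NS, M_PER_S_TO_A_PER_NS

Mode = Literal["diffusion", "flow"]

__all__ = [
    "EnergyGrid",
    "Delta",
    "Lorentzian",
    "Gaussian",
    "Voigt",
    "ModelTermSet",
    "LipidParams",
    "PeptideParams",
    "ExtendedLipidParams",
    "lorentzian",
    "gaussian",
    "build_lipid_model",
    "build_membrane_model",
    "build_extended_model",
    "gamma_from_D",
    "D_from_gamma",
    "sigma_from_v0",
    "v0_from_sigma",
]


# ---------------------------------------------------------------------------
# energy grid


@dataclass(frozen=True)
class EnergyGrid:
    """Equidistant energy-transfer grid (ueV) that brackets omega = 0."""

    omega: np.ndarray

    def __post_init__(self) -> None:
        om = np.asarray(self.omega, dtype=float)
        if om.ndim != 1 or om.size < 2:
            raise ValueError("energy grid needs at least two points")
        steps = np.diff(om)
        if np.any(steps <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=0.0):
            raise ValueError("energy grid must be equidistant")
        if om[0] > 0 or om[-1] < 0:
            raise ValueError("energy grid must contain or bracket omega = 0")
        object.__setattr__(self, "omega", om)

    @property
    def bin_width(self) -> float:
        return float(self.omega[1] - self.omega[0])

    @property
    def n_bins(self) -> int:
        return self.omega.size

    @classmethod
    def symmetric(cls, omega_max: float = 30.0, bin_width: float = 0.1) -> "EnergyGrid":
        """Symmetric grid [-omega_max, omega_max] with the given bin width."""
        n = int(round(omega_max / bin_width))
        return cls(np.arange(-n, n + 1) * bin_width)

    def extended(self, pad_bins: int) -> "EnergyGrid":
        """Grid padded by ``pad_bins`` bins on each side (for convolutions)."""
        w = self.bin_width
        left = self.omega[0] - w * np.arange(pad_bins, 0, -1)
        right = self.omega[-1] + w * np.arange(1, pad_bins + 1)
        return EnergyGrid(np.concatenate([left, self.omega, right]))


# ---------------------------------------------------------------------------
# elementary line shapes


def lorentzian(hwhm: float, omega) -> np.ndarray | float:
    """Unit-area Lorentzian ``(1/pi) * hwhm / (hwhm^2 + omega^2)``, 1/ueV."""
    if hwhm <= 0:
        raise ValueError(f"Lorentzian HWHM must be positive, got {hwhm}")
    omega = np.asarray(omega, dtype=float)
    out = (hwhm / np.pi) / (hwhm * hwhm + omega * omega)
    return out if out.ndim else float(out)


def gaussian(sd: float, omega) -> np.ndarray | float:
    """Unit-area Gaussian ``exp(-omega^2/(2 sd^2)) / (sd sqrt(2 pi))``, 1/ueV."""
    if sd <= 0:
        raise ValueError(f"Gaussian standard deviation must be positive, got {sd}")
    omega = np.asarray(omega, dtype=float)
    out = np.exp(-0.5 * (omega / sd) ** 2) / (sd * np.sqrt(2.0 * np.pi))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Delta:
    """Elastic delta component; takes the resolution shape on convolution."""


@dataclass(frozen=True)
class Lorentzian:
    hwhm: float

    def __post_init__(self) -> None:
        if self.hwhm <= 0:
            raise ValueError("Lorentzian HWHM must be positive")

    def density(self, omega) -> np.ndarray:
        return lorentzian(self.hwhm, omega)


@dataclass(frozen=True)
class Gaussian:
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("Gaussian sd must be positive")

    def density(self, omega) -> np.ndarray:
        return gaussian(self.sd, omega)


@dataclass(frozen=True)
class Voigt:
    """Gaussian (sd) convolved with Lorentzian (hwhm); exact profile."""

    sd: float
    hwhm: float

    def __post_init__(self) -> None:
        if self.sd <= 0 or self.hwhm <= 0:
            raise ValueError("Voigt widths must be positive")

    def density(self, omega) -> np.ndarray:
        return voigt_profile(np.asarray(omega, dtype=float), self.sd, self.hwhm)


Shape = Union[Delta, Lorentzian, Gaussian, Voigt]


def _convolve_shapes(a: Shape, b: Shape) -> Shape:
    """Analytic convolution of two centred line shapes."""
    if isinstance(a, Delta):
        return b
    if isinstance(b, Delta):
        return a
    if isinstance(a, Lorentzian) and isinstance(b, Lorentzian):
        return Lorentzian(a.hwhm + b.hwhm)
    if isinstance(a, Gaussian) and isinstance(b, Gaussian):
        return Gaussian(float(np.hypot(a.sd, b.sd)))
    if isinstance(a, Gaussian) and isinstance(b, Lorentzian):
        return Voigt(a.sd, b.hwhm)
    if isinstance(a, Lorentzian) and isinstance(b, Gaussian):
        return Voigt(b.sd, a.hwhm)
    if isinstance(a, Voigt) and isinstance(b, Lorentzian):
        return Voigt(a.sd, a.hwhm + b.hwhm)
    if isinstance(a, Lorentzian) and isinstance(b, Voigt):
        return Voigt(b.sd, a.hwhm + b.hwhm)
    if isinstance(a, Voigt) and isinstance(b, Gaussian):
        return Voigt(float(np.hypot(a.sd, b.sd)), a.hwhm)
    if isinstance(a, Gaussian) and isinstance(b, Voigt):
        return Voigt(float(np.hypot(a.sd, b.sd)), b.hwhm)
    if isinstance(a, Voigt) and isinstance(b, Voigt):
        return Voigt(float(np.hypot(a.sd, b.sd)), a.hwhm + b.hwhm)
    raise TypeError(f"cannot convolve {a!r} with {b!r}")


@dataclass(frozen=True)
class ModelTermSet:
    """Weighted sum of centred line shapes plus a flat background.

    ``terms`` is a tuple of ``(weight, shape)`` pairs; weights are
    dimensionless spectral weights, shapes are unit-area densities (1/ueV).
    ``flat_background`` is a constant spectral density c (same 1/ueV units).
    """

    terms: tuple[tuple[float, Shape], ...]
    flat_background: float = 0.0

    def __post_init__(self) -> None:
        for w, shape in self.terms:
            if not np.isfinite(w):
                raise ValueError("term weights must be finite")
            if w < 0:
                raise ValueError("term weights must be non-negative")
        if self.flat_background < 0:
            raise ValueError("flat background must be non-negative")

    @property
    def total_weight(self) -> float:
        """Sum of term weights (integrated intensity excluding background)."""
        return float(sum(w for w, _ in self.terms))

    def has_delta(self) -> bool:
        return any(isinstance(s, Delta) for _, s in self.terms)

    def evaluate(self, omega) -> np.ndarray:
        """Spectral density on ``omega``; delta terms cannot be discretized."""
        if self.has_delta():
            raise ValueError(
                "term set contains a delta component; convolve with a "
                "resolution kernel before evaluating on a grid"
            )
        omega = np.asarray(omega, dtype=float)
        out = np.full(omega.shape, self.flat_background, dtype=float)
        for w, shape in self.terms:
            if w:
                out += w * shape.density(omega)
        return out

    def convolved_with_gaussian(self, sd: float) -> "ModelTermSet":
        """Term set after analytic convolution with a Gaussian of given sd."""
        res = Gaussian(sd)
        return replace(
            self,
            terms=tuple((w, _convolve_shapes(shape, res)) for w, shape in self.terms),
        )

    def scaled(self, factor: float) -> "ModelTermSet":
        return ModelTermSet(
            terms=tuple((w * factor, s) for w, s in self.terms),
            flat_background=self.flat_background * factor,
        )

    def __add__(self, other: "ModelTermSet") -> "ModelTermSet":
        return ModelTermSet(
            terms=self.terms + other.terms,
            flat_background=self.flat_background + other.flat_background,
        )


# ---------------------------------------------------------------------------
# model parameters


@dataclass(frozen=True)
class LipidParams:
    """Per-Q parameters of the single-population lipid model.

    A_s       elastic incoherent structure factor of the slow localized motion
    Gamma_s   HWHM of the slow localized Lorentzian, ueV
    long_range  width of the long-range term: Lorentzian HWHM Gamma_lipid in
                diffusion mode, Gaussian sd sigma_lipid in flow mode (ueV)
    a         free per-Q amplitude (absorbs the Debye-Waller factor)
    """

    A_s: float
    Gamma_s: float
    long_range: float
    a: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.A_s <= 1.0:
            raise ValueError("EISF A_s must lie in [0, 1]")
        if self.Gamma_s <= 0 or self.long_range <= 0:
            raise ValueError("widths must be positive")
        if not np.isfinite(self.a) or self.a < 0:
            raise ValueError("amplitude a must be finite and non-negative")


@dataclass(frozen=True)
class PeptideParams:
    """Per-Q peptide component: EISF B_s, local and long-range Lorentzian
    widths (ueV), amplitude b and spectral weight p of the peptide."""

    B_s: float
    Gamma_s_peptide: float
    Gamma_peptide: float
    b: float = 1.0
    p: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.B_s <= 1.0:
            raise ValueError("EISF B_s must lie in [0, 1]")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("spectral weight p must lie in [0, 1]")
        if self.Gamma_s_peptide <= 0 or self.Gamma_peptide <= 0:
            raise ValueError("widths must be positive")


@dataclass(frozen=True)
class ExtendedLipidParams:
    """Two-population split of the lipid long-range term.

    l        fraction of non-interacting (free) lipids
    width_1  free-lipid long-range width (fixed from the pure-lipid fit), ueV
    width_2  slowed-lipid long-range width, ueV

    ``width_2 <= width_1`` is expected physically but deliberately not
    enforced; fits are allowed to find the opposite ordering.
    """

    l: float
    width_1: float
    width_2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.l <= 1.0:
            raise ValueError("free-lipid fraction l must lie in [0, 1]")
        if self.width_1 <= 0 or self.width_2 <= 0:
            raise ValueError("widths must be positive")


# ---------------------------------------------------------------------------
# model builders


def _long_range_shape(width: float, mode: Mode) -> Shape:
    if mode == "diffusion":
        return Lorentzian(width)
    if mode == "flow":
        return Gaussian(width)
    raise ValueError(f"unknown mode {mode!r}; expected 'diffusion' or 'flow'")


def _component(
    amplitude: float, eisf: float, gamma_local: float, width: float, mode: Mode
) -> tuple[tuple[float, Shape], ...]:
    """Expand long_range (x) [eisf * delta + (1-eisf) * L(gamma_local)]."""
    lr = _long_range_shape(width, mode)
    terms: list[tuple[float, Shape]] = []
    if eisf > 0.0:
        terms.append((amplitude * eisf, lr))
    if eisf < 1.0:
        terms.append(
            (amplitude * (1.0 - eisf), _convolve_shapes(lr, Lorentzian(gamma_local)))
        )
    return tuple(terms)


def build_lipid_model(
    params: LipidParams, mode: Mode, background: float = 0.0
) -> ModelTermSet:
    """Single-population lipid model: long-range shape convolved with the
    localized term, weighted by the amplitude ``a``, plus flat background."""
    return ModelTermSet(
        terms=_component(params.a, params.A_s, params.Gamma_s, params.long_range, mode),
        flat_background=background,
    )


def _peptide_terms(peptide: PeptideParams) -> tuple[tuple[float, Shape], ...]:
    return _component(
        peptide.p * peptide.b,
        peptide.B_s,
        peptide.Gamma_s_peptide,
        peptide.Gamma_peptide,
        "diffusion",
    )


def build_membrane_model(
    lipid: LipidParams, peptide: PeptideParams, mode: Mode, background: float = 0.0
) -> ModelTermSet:
    """Peptide-loaded membrane: p-weighted peptide component (always
    Lorentzian long-range) plus (1-p)-weighted lipid component."""
    lip_terms = _component(
        (1.0 - peptide.p) * lipid.a, lipid.A_s, lipid.Gamma_s, lipid.long_range, mode
    )
    return ModelTermSet(
        terms=_peptide_terms(peptide) + lip_terms, flat_background=background
    )


def build_extended_model(
    lipid: LipidParams,
    peptide: PeptideParams,
    ext: ExtendedLipidParams,
    mode: Mode,
    background: float = 0.0,
) -> ModelTermSet:
    """Two-population membrane model: the lipid term is split into a fraction
    ``l`` of free lipids at ``width_1`` and ``1-l`` of slowed lipids at
    ``width_2``; both populations share ``A_s`` and ``Gamma_s``."""
    free = _component(
        (1.0 - peptide.p) * ext.l * lipid.a,
        lipid.A_s,
        lipid.Gamma_s,
        ext.width_1,
        mode,
    )
    slowed = _component(
        (1.0 - peptide.p) * (1.0 - ext.l) * lipid.a,
        lipid.A_s,
        lipid.Gamma_s,
        ext.width_2,
        mode,
    )
    return ModelTermSet(
        terms=_peptide_terms(peptide) + free + slowed, flat_background=background
    )


# ---------------------------------------------------------------------------
# dispersion relations


def gamma_from_D(Q: float, D_cm2_s: float) -> float:
    """Lorentzian HWHM (ueV) of continuous diffusion: Gamma = hbar * D * Q^2."""
    if Q < 0 or D_cm2_s < 0:
        raise ValueError("Q and D must be non-negative")
    return HBAR_UEV_NS * D_cm2_s * CM2_PER_S_TO_A2_PER_NS * Q * Q


def D_from_gamma(Q: float, gamma_uev: float) -> float:
    """Inverse of :func:`gamma_from_D`; returns D in cm^2/s."""
    if Q <= 0:
        raise ValueError("Q must be positive")
    if gamma_uev < 0:
        raise ValueError("width must be non-negative")
    return gamma_uev / (HBAR_UEV_NS * Q * Q) / CM2_PER_S_TO_A2_PER_NS


def sigma_from_v0(Q: float, v0_m_s: float) -> float:
    """Gaussian sd (ueV) of flow-like motion: sigma = hbar * v0 * Q."""
    if Q < 0 or v0_m_s < 0:
        raise ValueError("Q and v0 must be non-negative")
    return HBAR_UEV_NS * v0_m_s * M_PER_S_TO_A_PER_NS * Q


def v0_from_sigma(Q: float, sigma_uev: float) -> float:
    """Inverse of :func:`sigma_from_v0`; returns v0 in m/s."""
    if Q <= 0:
        raise ValueError("Q must be positive")
    if sigma_uev < 0:
        raise ValueError("width must be non-negative")
    return sigma_uev / (HBAR_UEV_NS * Q) / M_PER_S_TO_A_PER_NS
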