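"""Synthetic forward model of a backscattering QENS measurement.

Emulates a high-resolution backscattering experiment on lipid vesicles:
a Gaussian instrument resolution (default 0.75 ueV FWHM), an energy window of
+-30 ueV binned at 0.1 ueV, Poisson counting statistics, and the dynamical
parameters of the membrane scenarios under study (pure lipid, peptide-loaded,
and the two-population extension).  Also generates 2D Brownian trajectories
that stand in for molecular-dynamics centre-of-mass data in the MSD analysis.

The generator and the fitting code share the analytic convolution algebra of
:mod:`qensmem.models`; a direct-summation numerical convolution path is kept
for tabulated (non-Gaussian) kernels and serves as an independent cross-check
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import spherical_jn

from .constants import CM2_PER_S_TO_A2_PER_NS, FWHM_PER_SIGMA
from .models import (
    Delta,
    EnergyGrid,
    ExtendedLipidParams,
    LipidParams,
    Mode,
    ModelTermSet,
    PeptideParams,
    build_extended_model,
    build_lipid_model,
    build_membrane_model,
    gamma_from_D,
    sigma_from_v0,
)

__all__ = [
    "ResolutionKernel",
    "Spectrum",
    "Trajectory",
    "SyntheticDataset",
    "make_resolution",
    "convolve",
    "generate_spectrum",
    "generate_dataset",
    "generate_background",
    "generate_trajectories",
    "sphere_eisf",
    "DEFAULT_Q_SET",
]

#: Default momentum transfers (1/A): the three printed values plus two
#: interpolated points so the dispersion regressions have >= 4 supports.
DEFAULT_Q_SET: tuple[float, ...] = (0.29, 0.44, 0.57, 0.78, 0.95)

#: Default slow localized HWHM (ueV) used by the generator for lipid and
#: peptide internal motions; well inside the +-30 ueV window.
DEFAULT_GAMMA_S = 5.0

#: Default flat background density (1/ueV) relative to unit model weight.
DEFAULT_BACKGROUND = 0.002

#: Default radius (A) of the sphere-diffusion EISF used only for generation.
DEFAULT_EISF_RADIUS = 2.0


@dataclass(frozen=True)
class ResolutionKernel:
    """Normalized instrument response on an energy grid.

    ``gaussian_sd`` is set when the kernel is an exact discrete Gaussian, in
    which case convolutions are carried out analytically; a tabulated kernel
    (``gaussian_sd=None``) falls back to numerical convolution.
    """

    grid: EnergyGrid
    values: np.ndarray
    fwhm: float | None = None
    gaussian_sd: float | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.grid.omega.shape:
            raise ValueError("kernel values must match the grid")
        if np.any(vals < 0):
            raise ValueError("kernel values must be non-negative")
        area = vals.sum() * self.grid.bin_width
        if abs(area - 1.0) > 1e-9:
            raise ValueError(f"kernel area must be 1, got {area}")
        if vals.argmax() != np.argmin(np.abs(self.grid.omega)):
            raise ValueError("kernel must peak at omega = 0")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class Spectrum:
    """One Q-slice of S(Q, omega) with per-bin uncertainties."""

    Q: float
    grid: EnergyGrid
    intensity: np.ndarray
    uncertainty: np.ndarray

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensity, dtype=float)
        unc = np.asarray(self.uncertainty, dtype=float)
        if inten.shape != self.grid.omega.shape or unc.shape != inten.shape:
            raise ValueError("intensity/uncertainty must match the grid length")
        object.__setattr__(self, "intensity", inten)
        object.__setattr__(self, "uncertainty", unc)


@dataclass(frozen=True)
class Trajectory:
    """Per-molecule 2D centre-of-mass positions on a shared time base.

    times      (n_frames,) ns, equidistant and strictly increasing
    positions  (n_molecules, n_frames, 2) in Angstrom
    """

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        pos = np.asarray(self.positions, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if pos.ndim != 3 or pos.shape[1] != t.size or pos.shape[2] != 2:
            raise ValueError("positions must have shape (n_mol, n_frames, 2)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", pos)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


def make_resolution(grid: EnergyGrid, fwhm: float = 0.75) -> ResolutionKernel:
    """Discrete Gaussian resolution kernel, renormalized to unit grid area."""
    if fwhm <= 0:
        raise ValueError("resolution FWHM must be positive")
    if grid.omega[-1] < 10 * fwhm or grid.omega[0] > -10 * fwhm:
        raise ValueError("grid must cover at least +-10 FWHM of the resolution")
    sd = fwhm / FWHM_PER_SIGMA
    vals = np.exp(-0.5 * (grid.omega / sd) ** 2)
    vals /= vals.sum() * grid.bin_width
    return ResolutionKernel(grid=grid, values=vals, fwhm=fwhm, gaussian_sd=sd)


def convolve(model: ModelTermSet, kernel: ResolutionKernel) -> np.ndarray:
    """Spectral density of ``model`` convolved with the resolution kernel.

    Delta terms map exactly onto the kernel line shape (for a parametric
    Gaussian kernel, onto the analytic Gaussian); all other shapes are
    composed analytically when the kernel is Gaussian and numerically (direct
    summation on a padded grid) otherwise.
    """
    grid = kernel.grid
    if kernel.gaussian_sd is not None:
        smeared = model.convolved_with_gaussian(kernel.gaussian_sd)
        om = grid.omega
        n = om.size
        # all shapes are centred, so exploit grid symmetry where possible
        if n % 2 == 1 and om[n // 2] == 0.0 and np.array_equal(om[n // 2 :], -om[: n // 2 + 1][::-1]):
            half = smeared.evaluate(om[n // 2 :])
            return np.concatenate([half[:0:-1], half])
        return smeared.evaluate(om)

    out = np.full(grid.n_bins, model.flat_background, dtype=float)
    delta_weight = 0.0
    smooth_terms = []
    for w, shape in model.terms:
        if isinstance(shape, Delta):
            delta_weight += w
        elif w:
            smooth_terms.append((w, shape))
    out += delta_weight * kernel.values
    if smooth_terms:
        pad = grid.n_bins // 2 + 1
        ext = grid.extended(pad)
        dens = np.zeros(ext.n_bins)
        for w, shape in smooth_terms:
            dens += w * shape.density(ext.omega)
        conv = np.convolve(dens, kernel.values, mode="same") * grid.bin_width
        out += conv[pad : pad + grid.n_bins]
    return out


def generate_spectrum(
    model: ModelTermSet,
    kernel: ResolutionKernel,
    total_counts: int,
    rng: np.random.Generator | int | None = None,
    Q: float = 0.0,
) -> Spectrum:
    """Poisson-sampled spectrum whose noiseless expectation sums to
    ``total_counts`` over the grid; uncertainty is sqrt(max(count, 1))."""
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    rng = np.random.default_rng(rng)
    density = convolve(model, kernel)
    expected = density * kernel.grid.bin_width
    expected *= total_counts / expected.sum()
    counts = rng.poisson(expected).astype(float)
    unc = np.sqrt(np.maximum(counts, 1.0))
    return Spectrum(Q=Q, grid=kernel.grid, intensity=counts, uncertainty=unc)


def sphere_eisf(Q: float, radius: float = DEFAULT_EISF_RADIUS) -> float:
    """EISF of diffusion inside a sphere, [3 j1(QR)/(QR)]^2; -> 1 as Q -> 0."""
    x = Q * radius
    if x == 0.0:
        return 1.0
    return float((3.0 * spherical_jn(1, x) / x) ** 2)


Scenario = Literal["pure_lipid", "lipid_peptide", "extended"]


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated spectra plus the kernel and generating ground truth."""

    spectra: list[Spectrum]
    kernel: ResolutionKernel
    truth: dict


def _scenario_model(
    scenario: Scenario,
    mode: Mode,
    Q: float,
    *,
    D_lipid: float,
    v0_lipid: float,
    D_peptide: float,
    p: float,
    influenced_fraction: float,
    D_free: float,
    v0_free: float,
    gamma_s: float,
    eisf_radius: float,
    background: float,
) -> tuple[ModelTermSet, dict]:
    """Model term set and ground-truth record for one Q value."""
    if mode == "diffusion":
        lip_width = gamma_from_D(Q, D_lipid)
    else:
        lip_width = sigma_from_v0(Q, v0_lipid)
    A_s = sphere_eisf(Q, eisf_radius)
    lipid = LipidParams(A_s=A_s, Gamma_s=gamma_s, long_range=lip_width, a=1.0)
    truth = {"Q": Q, "A_s": A_s, "Gamma_s": gamma_s, "lipid_width": lip_width}

    if scenario == "pure_lipid":
        return build_lipid_model(lipid, mode, background), truth

    gamma_pep = gamma_from_D(Q, D_peptide)
    peptide = PeptideParams(
        B_s=A_s, Gamma_s_peptide=gamma_s, Gamma_peptide=gamma_pep, b=1.0, p=p
    )
    truth.update({"peptide_width": gamma_pep, "p": p})
    if scenario == "lipid_peptide":
        return build_membrane_model(lipid, peptide, mode, background), truth

    if scenario == "extended":
        if mode == "diffusion":
            width_1 = gamma_from_D(Q, D_free)
        else:
            width_1 = sigma_from_v0(Q, v0_free)
        ext = ExtendedLipidParams(
            l=1.0 - influenced_fraction, width_1=width_1, width_2=lip_width
        )
        truth.update(
            {"width_1": width_1, "width_2": lip_width, "l": 1.0 - influenced_fraction}
        )
        return build_extended_model(lipid, peptide, ext, mode, background), truth

    raise ValueError(f"unknown scenario {scenario!r}")


def generate_dataset(
    scenario: Scenario,
    mode: Mode,
    *,
    D_lipid: float = 21e-8,
    v0_lipid: float = 0.27,
    D_peptide: float = 0.5e-8,
    p: float = 0.2,
    influenced_fraction: float = 0.8,
    D_free: float = 21e-8,
    v0_free: float = 0.27,
    Q_set: Sequence[float] = DEFAULT_Q_SET,
    counts: int = 1_000_000,
    omega_max: float = 30.0,
    bin_width: float = 0.1,
    fwhm: float = 0.75,
    gamma_s: float = DEFAULT_GAMMA_S,
    eisf_radius: float = DEFAULT_EISF_RADIUS,
    background: float = DEFAULT_BACKGROUND,
    seed: int | None = None,
) -> SyntheticDataset:
    """Generate one Poisson-noisy spectrum per Q for a membrane scenario.

    Defaults reproduce the backscattering study conditions: Q in
    0.29-0.95 1/A, +-30 ueV window at 0.1 ueV bins, 0.75 ueV FWHM Gaussian
    resolution, 1e6 counts per spectrum, and the reported transport values
    (pure-lipid D = 21e-8 cm^2/s, v0 = 0.27 m/s, peptide D = 0.5e-8 cm^2/s,
    peptide spectral weight p = 0.2 for protonated lipid contrast).

    In the ``extended`` scenario ``influenced_fraction`` of the lipid weight
    is generated at the slowed width (from ``D_lipid``/``v0_lipid``) and the
    rest at the free width (from ``D_free`` in diffusion mode, ``v0_free`` in
    flow mode).
    """
    if not all(0.1 <= q <= 2.0 for q in Q_set):
        raise ValueError("Q values must lie within [0.1, 2.0] 1/A")
    rng = np.random.default_rng(seed)
    grid = EnergyGrid.symmetric(omega_max, bin_width)
    kernel = make_resolution(grid, fwhm)
    spectra: list[Spectrum] = []
    truths: list[dict] = []
    for Q in Q_set:
        model, truth = _scenario_model(
            scenario,
            mode,
            Q,
            D_lipid=D_lipid,
            v0_lipid=v0_lipid,
            D_peptide=D_peptide,
            p=p,
            influenced_fraction=influenced_fraction,
            D_free=D_free,
            v0_free=v0_free,
            gamma_s=gamma_s,
            eisf_radius=eisf_radius,
            background=background,
        )
        spectra.append(generate_spectrum(model, kernel, counts, rng, Q=Q))
        truths.append(truth)
    truth = {
        "scenario": scenario,
        "mode": mode,
        "D_lipid": D_lipid,
        "v0_lipid": v0_lipid,
        "D_peptide": D_peptide,
        "p": p,
        "influenced_fraction": influenced_fraction,
        "per_Q": truths,
    }
    return SyntheticDataset(spectra=spectra, kernel=kernel, truth=truth)


def generate_background(
    level: float,
    kernel: ResolutionKernel,
    rng: np.random.Generator | int | None = None,
    Q: float = 0.0,
) -> Spectrum:
    """Quasi-flat noisy background spectrum (e.g. solvent) for reduction
    tests; ``level`` is the mean expected count per bin at the window centre."""
    if level < 0:
        raise ValueError("background level must be non-negative")
    rng = np.random.default_rng(rng)
    om = kernel.grid.omega
    halfwidth = 4.0 * (om[-1] - om[0])  # very broad Lorentzian: ~flat in window
    expected = level / (1.0 + (om / halfwidth) ** 2)
    counts = rng.poisson(expected).astype(float)
    unc = np.sqrt(np.maximum(counts, 1.0))
    return Spectrum(Q=Q, grid=kernel.grid, intensity=counts, uncertainty=unc)


def generate_trajectories(
    D_cm2_s: float,
    n_mol: int,
    dt: float,
    t_max: float,
    seed: int | None = None,
) -> Trajectory:
    """Independent 2D Brownian walks with per-axis step sd sqrt(2 D dt)."""
    if D_cm2_s < 0:
        raise ValueError("D must be non-negative")
    if dt <= 0 or t_max <= 0:
        raise ValueError("dt and t_max must be positive")
    rng = np.random.default_rng(seed)
    n_frames = int(round(t_max / dt)) + 1
    times = np.arange(n_frames) * dt
    step_sd = np.sqrt(2.0 * D_cm2_s * CM2_PER_S_TO_A2_PER_NS * dt)
    steps = rng.normal(0.0, step_sd, size=(n_mol, n_frames - 1, 2)) if step_sd else np.zeros(
        (n_mol, n_frames - 1, 2)
    )
    positions = np.concatenate(
        [np.zeros((n_mol, 1, 2)), np.cumsum(steps, axis=1)], axis=1
    )
    return Trajectory(times=times, positions=positions)
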