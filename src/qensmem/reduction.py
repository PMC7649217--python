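"""Simplified spectrum reduction: vanadium normalization, scaled background
subtraction, and energy rebinning.

The pipeline assumes generator-level ideality (no absorption or empty-can
corrections); uncertainties are propagated in quadrature throughout and
negative post-subtraction bins are kept so chi-squared statistics stay
unbiased.
"""

from __future__ import annotations

import numpy as np

from .instrument import Spectrum
from .models import EnergyGrid

__all__ = ["normalize_to_vanadium", "subtract_scaled_background", "rebin_energy"]


def _check_grids(a: Spectrum, b: Spectrum) -> None:
    if a.grid.omega.shape != b.grid.omega.shape or not np.allclose(
        a.grid.omega, b.grid.omega
    ):
        raise ValueError("spectra must share the same energy grid")


def normalize_to_vanadium(sample: Spectrum, vanadium: Spectrum) -> Spectrum:
    """Divide by the elastic-line integral of the vanadium measurement.

    Vanadium scatters purely elastically, so its integrated intensity
    calibrates the detector sensitivity at this Q.  The (small) uncertainty
    of the vanadium integral is propagated in quadrature.
    """
    _check_grids(sample, vanadium)
    bw = vanadium.grid.bin_width
    integral = float(vanadium.intensity.sum()) * bw
    if integral == 0.0:
        raise ValueError("vanadium elastic-line integral is zero")
    integral_err = float(np.sqrt(np.sum(vanadium.uncertainty**2))) * bw
    intensity = sample.intensity / integral
    unc = np.sqrt(
        (sample.uncertainty / integral) ** 2
        + (sample.intensity * integral_err / integral**2) ** 2
    )
    return Spectrum(Q=sample.Q, grid=sample.grid, intensity=intensity, uncertainty=unc)


def subtract_scaled_background(
    sample: Spectrum, background: Spectrum, scale: float
) -> Spectrum:
    """``sample - scale * background`` with quadrature errors; negative bins
    are permitted (not clipped)."""
    if scale < 0:
        raise ValueError("background scale must be non-negative")
    _check_grids(sample, background)
    intensity = sample.intensity - scale * background.intensity
    unc = np.sqrt(sample.uncertainty**2 + (scale * background.uncertainty) ** 2)
    return Spectrum(Q=sample.Q, grid=sample.grid, intensity=intensity, uncertainty=unc)


def rebin_energy(sample: Spectrum, step: float = 0.1) -> Spectrum:
    """Rebin counts to equidistant steps of ``step`` ueV.

    Counts are summed into the new bins (total intensity conserved exactly)
    and uncertainties combined in quadrature.  When ``step`` is not an exact
    multiple of the native width, each native bin is assigned to the new bin
    whose centre is nearest (nearest-edge convention).
    """
    native = sample.grid.bin_width
    if step < native - 1e-12:
        raise ValueError("rebin step must be at least the native bin width")
    if abs(step - native) < 1e-12:
        return sample
    om = sample.grid.omega
    # new bin centres anchored at omega = 0 so the grid still brackets zero
    idx = np.round(om / step).astype(int)
    new_idx = np.arange(idx.min(), idx.max() + 1)
    new_omega = new_idx * step
    intensity = np.zeros(new_idx.size)
    var = np.zeros(new_idx.size)
    pos = idx - idx.min()
    np.add.at(intensity, pos, sample.intensity)
    np.add.at(var, pos, sample.uncertainty**2)
    return Spectrum(
        Q=sample.Q,
        grid=EnergyGrid(new_omega),
        intensity=intensity,
        uncertainty=np.sqrt(var),
    )
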