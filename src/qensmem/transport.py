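"""Transport coefficients and interaction geometry from fitted line widths.

Diffusive line widths obey the dispersion relation Gamma = hbar * D * Q^2 and
flow-like widths sigma = hbar * v0 * Q; the transport coefficients are the
slopes of error-weighted regressions through the origin (an intercept option
exists for diagnostics only -- physically Gamma(0) = sigma(0) = 0).

The two-population fit yields the fraction of lipids whose long-range motion
is slowed by the transmembrane peptide; combined with molecular areas this
gives a peptide-lipid interaction radius via a per-leaflet disc model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import CM2_PER_S_TO_A2_PER_NS, HBAR_UEV_NS, M_PER_S_TO_A_PER_NS

__all__ = [
    "DispersionData",
    "InteractionGeometry",
    "fit_diffusion",
    "fit_velocity",
    "interaction_radius",
    "lipids_per_peptide",
]


@dataclass(frozen=True)
class DispersionData:
    """Fitted widths (Gamma or sigma, ueV) vs momentum transfer (1/A)."""

    Q: np.ndarray
    width: np.ndarray
    width_err: np.ndarray | None = None

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        w = np.asarray(self.width, dtype=float)
        if Q.size != w.size or Q.size < 2:
            raise ValueError("need >= 2 matching (Q, width) points")
        if np.any(w < 0):
            raise ValueError("widths must be non-negative")
        err = self.width_err
        if err is not None:
            err = np.asarray(err, dtype=float)
            if err.size != Q.size or np.any(err < 0):
                raise ValueError("width_err must match Q and be non-negative")
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "width", w)
        object.__setattr__(self, "width_err", err)


def _origin_slope(
    x: np.ndarray, y: np.ndarray, err: np.ndarray | None
) -> tuple[float, float]:
    """Error-weighted least-squares slope of y = s*x through the origin."""
    if np.allclose(x, 0.0):
        raise ValueError("degenerate abscissa: all values zero")
    if err is not None and np.all(err > 0):
        w = 1.0 / err**2
    else:
        w = np.ones_like(x)
    sxx = float(np.sum(w * x * x))
    slope = float(np.sum(w * x * y)) / sxx
    if err is not None and np.all(err > 0):
        slope_err = float(np.sqrt(1.0 / sxx))
    else:  # scatter-based error estimate
        resid = y - slope * x
        dof = max(x.size - 1, 1)
        slope_err = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    return slope, slope_err


def fit_diffusion(data: DispersionData) -> tuple[float, float]:
    """Apparent self-diffusion coefficient from Gamma vs Q^2.

    Returns ``(D, D_err)`` in cm^2/s from the origin-constrained weighted
    regression of the Lorentzian HWHMs against Q^2.
    """
    slope, err = _origin_slope(data.Q**2, data.width, data.width_err)
    conv = HBAR_UEV_NS * CM2_PER_S_TO_A2_PER_NS
    return slope / conv, err / conv


def fit_velocity(data: DispersionData) -> tuple[float, float]:
    """Most probable flow velocity from sigma vs Q.

    Returns ``(v0, v0_err)`` in m/s from the origin-constrained weighted
    regression of the Gaussian standard deviations against Q.
    """
    slope, err = _origin_slope(data.Q, data.width, data.width_err)
    conv = HBAR_UEV_NS * M_PER_S_TO_A_PER_NS
    return slope / conv, err / conv


@dataclass(frozen=True)
class InteractionGeometry:
    """Inputs of the per-leaflet disc model of the influenced lipid annulus.

    influenced_fraction   fraction (1 - l) of lipids slowed by the peptide
    lipids_per_peptide    lipids per peptide counting both leaflets
    A_DMPC, A_TFRC        effective in-membrane molecular areas, A^2
    """

    influenced_fraction: float
    lipids_per_peptide: float
    A_DMPC: float = 60.0
    A_TFRC: float = 66.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.influenced_fraction <= 1.0:
            raise ValueError("influenced_fraction must lie in [0, 1]")
        if self.lipids_per_peptide <= 0:
            raise ValueError("lipids_per_peptide must be positive")
        if self.A_DMPC <= 0 or self.A_TFRC <= 0:
            raise ValueError("molecular areas must be positive")


def interaction_radius(geom: InteractionGeometry) -> float:
    """Peptide-lipid interaction radius in nm.

    The transmembrane peptide spans both leaflets, so the influenced lipids
    are split evenly between the two monolayers: the influenced disc in one
    leaflet has area ``A_TFRC + f * (N/2) * A_DMPC`` and the radius is
    ``sqrt(area / pi)``, converted from Angstrom to nm.
    """
    area = geom.A_TFRC + geom.influenced_fraction * (
        geom.lipids_per_peptide / 2.0
    ) * geom.A_DMPC
    return float(np.sqrt(area / np.pi)) / 10.0


def lipids_per_peptide(mole_percent_peptide: float) -> float:
    """Lipids per peptide for a peptide mole fraction given in percent."""
    if not 0.0 < mole_percent_peptide < 100.0:
        raise ValueError("mole percent must lie strictly between 0 and 100")
    return (100.0 - mole_percent_peptide) / mole_percent_peptide
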