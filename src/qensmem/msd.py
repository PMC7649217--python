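"""Mean-square-displacement analysis of 2D centre-of-mass trajectories.

The lateral diffusion coefficient follows from the Einstein relation
MSD(t) = 4 D t in two dimensions; the slope is taken over the linear window
of the MSD curve (2-5 ns by default, matching the regime where ballistic and
cage effects have decayed but statistics are still good).  Long runs are
split into disjoint windows (60 ns by default) to give independent estimates.
Time origins overlap within a window for variance reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import CM2_PER_S_TO_A2_PER_NS
from .instrument import Trajectory

__all__ = ["MsdCurve", "compute_msd", "diffusion_from_msd", "windowed_diffusion"]


@dataclass(frozen=True)
class MsdCurve:
    """Time- and ensemble-averaged MSD per lag: lags in ns, msd in A^2,
    n_pairs the number of (molecule, origin) pairs averaged per lag."""

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        msd = np.asarray(self.msd, dtype=float)
        if np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(msd < 0):
            raise ValueError("MSD must be non-negative")
        if lags[0] == 0.0 and msd[0] != 0.0:
            raise ValueError("MSD at zero lag must be zero")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "msd", msd)
        object.__setattr__(self, "n_pairs", np.asarray(self.n_pairs, dtype=int))


def compute_msd(traj: Trajectory, max_lag: float) -> MsdCurve:
    """MSD over all molecules and all (overlapping) time origins."""
    if traj.positions.shape[0] == 0:
        raise ValueError("trajectory contains no molecules")
    if max_lag >= traj.duration:
        raise ValueError("max_lag must be smaller than the trajectory duration")
    dt = traj.dt
    n_frames = traj.times.size
    n_mol = traj.positions.shape[0]
    k_max = int(np.floor(max_lag / dt + 1e-9))
    lags = np.arange(k_max + 1) * dt
    msd = np.zeros(k_max + 1)
    n_pairs = np.empty(k_max + 1, dtype=int)
    n_pairs[0] = n_mol * n_frames
    pos = traj.positions
    for k in range(1, k_max + 1):
        disp = pos[:, k:, :] - pos[:, :-k, :]
        msd[k] = float(np.mean(np.sum(disp**2, axis=-1)))
        n_pairs[k] = n_mol * (n_frames - k)
    return MsdCurve(lags=lags, msd=msd, n_pairs=n_pairs)


def diffusion_from_msd(
    curve: MsdCurve,
    fit_window: tuple[float, float] = (2.0, 5.0),
    dim: int = 2,
) -> tuple[float, float]:
    """Diffusion coefficient from the linear MSD regime.

    Least-squares line (with intercept) over the lag window; the slope gives
    ``D = slope / (2 * dim)``, returned in cm^2/s with its standard error.
    """
    lo, hi = fit_window
    mask = (curve.lags >= lo - 1e-9) & (curve.lags <= hi + 1e-9)
    if mask.sum() < 2:
        raise ValueError("fit window must contain at least two MSD points")
    t = curve.lags[mask]
    y = curve.msd[mask]
    (slope, _), cov = np.polyfit(t, y, 1, cov=True)
    slope_err = float(np.sqrt(cov[0, 0]))
    factor = 2.0 * dim * CM2_PER_S_TO_A2_PER_NS
    return float(slope) / factor, slope_err / factor


def windowed_diffusion(
    traj: Trajectory,
    window: float = 60.0,
    fit_window: tuple[float, float] = (2.0, 5.0),
    dim: int = 2,
) -> list[tuple[float, float]]:
    """Per-window diffusion estimates from disjoint time intervals.

    The trajectory is cut into consecutive ``window``-ns intervals (a final
    partial interval is dropped) and the MSD slope fit is repeated in each.
    Returns a list of ``(D, D_err)`` in cm^2/s.
    """
    if traj.duration + 1e-9 < window:
        raise ValueError("trajectory shorter than one window")
    steps_per_window = int(round(window / traj.dt))
    # consecutive windows share their boundary frame so every step is used once
    n_windows = (traj.times.size - 1) // steps_per_window
    estimates: list[tuple[float, float]] = []
    for w in range(n_windows):
        sl = slice(w * steps_per_window, (w + 1) * steps_per_window + 1)
        sub = Trajectory(
            times=traj.times[sl] - traj.times[sl][0],
            positions=traj.positions[:, sl, :],
        )
        curve = compute_msd(sub, max_lag=min(fit_window[1], sub.duration * 0.9))
        estimates.append(diffusion_from_msd(curve, fit_window=fit_window, dim=dim))
    return estimates
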