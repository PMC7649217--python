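"""Adaptive-step Metropolis fitting of convolved QENS models.

The sampler is a single-site random-walk Metropolis on the chi-squared
figure of merit: a proposal changing parameter ``theta_i`` is accepted with
probability ``exp(-dchi2/2)`` (uniform priors inside finite bounds).  Every
``adapt_every`` cycles each parameter's proposal width is rescaled toward a
target acceptance ratio of 0.66, ``w <- w * (rate/target)**0.5``.  The
retained chain (after a burn-in of one adaptation block) yields posterior
summaries and the histogram of chi-squared values -- the probability
distribution function used to rank competing models: the model whose PDF has
both its mode and its centre of mass at smaller chi-squared is preferred.

All Q slices are fitted jointly with per-Q amplitudes, EISFs and widths;
transport coefficients are extracted afterwards by dispersion regression
(see :mod:`qensmem.transport`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .instrument import ResolutionKernel, Spectrum, convolve
from .models import (
    ExtendedLipidParams,
    LipidParams,
    Mode,
    PeptideParams,
    build_extended_model,
    build_lipid_model,
    build_membrane_model,
)

__all__ = [
    "Param",
    "FitProblem",
    "SpectraFitProblem",
    "DirectProblem",
    "ChainResult",
    "Chi2Pdf",
    "ModelComparison",
    "chi_squared",
    "run_mcmc",
    "refine_start",
    "chi2_pdf",
    "compare_models",
    "lipid_fit_problem",
    "membrane_fit_problem",
    "membrane_contrast_pair_problem",
    "extended_fit_problem",
]


# ---------------------------------------------------------------------------
# problem definition


@dataclass
class Param:
    """One model parameter: starting value, finite bounds, proposal width.

    ``q_index`` marks per-Q parameters (only the corresponding spectrum needs
    re-evaluation when they move); ``None`` marks global parameters.
    """

    name: str
    init: float
    low: float
    high: float
    step: float
    fixed: bool = False
    q_index: int | None = None
    groups: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.low) and np.isfinite(self.high)):
            raise ValueError(f"parameter {self.name}: bounds must be finite")
        if not self.low <= self.init <= self.high:
            raise ValueError(f"parameter {self.name}: init outside bounds")
        if self.step <= 0:
            raise ValueError(f"parameter {self.name}: step must be positive")


class FitProblem:
    """Interface the sampler needs: parameters plus a groupwise chi2.

    Groups partition the chi-squared sum (one group per spectrum for joint
    fits) so single-site moves only re-evaluate the affected part.
    """

    params: list[Param]

    @property
    def n_groups(self) -> int:  # pragma: no cover - overridden
        raise NotImplementedError

    def group_chi2(self, group: int, theta: np.ndarray) -> float:
        raise NotImplementedError

    def groups_for(self, param_index: int) -> list[int]:
        p = self.params[param_index]
        if p.groups is not None:
            return list(p.groups)
        return list(range(self.n_groups)) if p.q_index is None else [p.q_index]

    def initial_theta(self) -> np.ndarray:
        return np.array([p.init for p in self.params], dtype=float)

    def chi2(self, theta: np.ndarray) -> float:
        return float(sum(self.group_chi2(g, theta) for g in range(self.n_groups)))

    def index(self, name: str) -> int:
        for i, p in enumerate(self.params):
            if p.name == name:
                return i
        raise KeyError(name)


class SpectraFitProblem(FitProblem):
    """Joint fit of a list of spectra with a per-Q expected-counts model."""

    def __init__(
        self,
        spectra: Sequence[Spectrum],
        kernel: ResolutionKernel,
        params: list[Param],
        expected_fn: Callable[[int, np.ndarray], np.ndarray],
    ) -> None:
        for s in spectra:
            if np.any(s.uncertainty <= 0):
                raise ValueError("spectra must have strictly positive uncertainties")
        self.spectra = list(spectra)
        self.kernel = kernel
        self.params = params
        self._expected = expected_fn

    @property
    def n_groups(self) -> int:
        return len(self.spectra)

    def expected(self, group: int, theta: np.ndarray) -> np.ndarray:
        return self._expected(group, theta)

    def group_chi2(self, group: int, theta: np.ndarray) -> float:
        s = self.spectra[group]
        r = (s.intensity - self._expected(group, theta)) / s.uncertainty
        return float(r @ r)


class DirectProblem(FitProblem):
    """Fit problem defined by an arbitrary chi2 function (single group);
    used for sampler validation on analytically tractable posteriors."""

    def __init__(self, params: list[Param], chi2_fn: Callable[[np.ndarray], float]):
        self.params = params
        self._chi2 = chi2_fn

    @property
    def n_groups(self) -> int:
        return 1

    def group_chi2(self, group: int, theta: np.ndarray) -> float:
        return float(self._chi2(theta))


def chi_squared(
    spectra: Sequence[Spectrum], model_values: Sequence[np.ndarray]
) -> float:
    """Sum over all Q and bins of ((data - model) / uncertainty)^2."""
    if len(spectra) != len(model_values):
        raise ValueError("one model array per spectrum required")
    total = 0.0
    for s, m in zip(spectra, model_values):
        m = np.asarray(m, dtype=float)
        if m.shape != s.intensity.shape:
            raise ValueError("model and spectrum grids do not match")
        if np.any(s.uncertainty <= 0):
            raise ValueError("uncertainties must be strictly positive")
        r = (s.intensity - m) / s.uncertainty
        total += float(r @ r)
    return total


# ---------------------------------------------------------------------------
# sampler


@dataclass
class ChainResult:
    """Retained MCMC chain with its chi-squared trace.

    ``samples`` holds full parameter vectors (fixed entries included) for the
    retained cycles; ``chi2_trace`` is aligned with ``samples``.
    """

    param_names: list[str]
    samples: np.ndarray
    chi2_trace: np.ndarray
    acceptance_rate: float
    burn_in: int
    thin: int
    final_steps: np.ndarray

    def column(self, name: str) -> np.ndarray:
        return self.samples[:, self.param_names.index(name)]

    def mean(self, name: str) -> float:
        return float(self.column(name).mean())

    def std(self, name: str) -> float:
        return float(self.column(name).std(ddof=1))

    def best(self) -> tuple[np.ndarray, float]:
        i = int(np.argmin(self.chi2_trace))
        return self.samples[i].copy(), float(self.chi2_trace[i])


def run_mcmc(
    problem: FitProblem,
    cycles: int = 1_000_000,
    adapt_every: int = 100_000,
    target_accept: float = 0.66,
    seed: int | None = None,
    burn_in: int | None = None,
    thin: int = 1,
) -> ChainResult:
    """Adaptive single-site Metropolis minimisation/sampling of chi-squared.

    One cycle proposes a Gaussian move of a single free parameter (round
    robin).  Moves outside the bounds are rejected outright.  At the end of
    each adaptation block every parameter's step is rescaled by
    ``(rate/target)**0.5`` with a Laplace-smoothed acceptance rate, clipped
    to a factor of 5 per block.  Burn-in defaults to one adaptation block.
    """
    if cycles <= 0:
        raise ValueError("cycles must be positive")
    rng = np.random.default_rng(seed)
    params = problem.params
    free = [i for i, p in enumerate(params) if not p.fixed]
    if not free:
        raise ValueError("no free parameters")
    if burn_in is None:
        burn_in = min(adapt_every, cycles // 2)

    theta = problem.initial_theta()
    steps = np.array([p.step for p in params], dtype=float)
    n_groups = problem.n_groups
    chi_q = np.array(
        [problem.group_chi2(g, theta) for g in range(n_groups)], dtype=float
    )
    chi2 = float(chi_q.sum())

    n_keep = max(0, (cycles - burn_in + thin - 1) // thin)
    samples = np.empty((n_keep, len(params)), dtype=float)
    trace = np.empty(n_keep, dtype=float)
    kept = 0

    accepted = np.zeros(len(params))
    proposed = np.zeros(len(params))
    last_rate = 0.0

    for c in range(cycles):
        i = free[c % len(free)]
        prop = theta[i] + steps[i] * rng.standard_normal()
        proposed[i] += 1
        if params[i].low <= prop <= params[i].high:
            old = theta[i]
            theta[i] = prop
            groups = problem.groups_for(i)
            new_vals = [problem.group_chi2(g, theta) for g in groups]
            dchi = sum(new_vals) - float(chi_q[groups].sum())
            if dchi <= 0.0 or rng.random() < math.exp(-min(dchi, 1400.0) / 2.0):
                chi_q[groups] = new_vals
                chi2 += dchi
                accepted[i] += 1
            else:
                theta[i] = old

        if c >= burn_in and (c - burn_in) % thin == 0:
            samples[kept] = theta
            trace[kept] = chi2
            kept += 1

        if (c + 1) % adapt_every == 0:
            block_prop = proposed[free].sum()
            block_acc = accepted[free].sum()
            if block_prop > 0 and block_acc == 0:
                raise RuntimeError(
                    "all proposals rejected during an adaptation block; "
                    "check starting values, bounds and step sizes"
                )
            last_rate = float(block_acc / max(block_prop, 1.0))
            if c + 1 < cycles:
                for i in free:
                    if proposed[i] > 0:
                        rate = (accepted[i] + 1.0) / (proposed[i] + 2.0)
                        factor = math.sqrt(rate / target_accept)
                        steps[i] *= min(max(factor, 0.2), 5.0)
                accepted[:] = 0.0
                proposed[:] = 0.0

    if proposed[free].sum() > 0:  # partial final block
        last_rate = float(accepted[free].sum() / proposed[free].sum())

    return ChainResult(
        param_names=[p.name for p in params],
        samples=samples[:kept],
        chi2_trace=trace[:kept],
        acceptance_rate=last_rate,
        burn_in=burn_in,
        thin=thin,
        final_steps=steps,
    )


def refine_start(problem: FitProblem, max_nfev: int | None = None) -> np.ndarray:
    """Weighted least-squares pre-fit used to seed the chain.

    Runs bounded least squares (trust-region reflective) on the free
    parameters and writes the solution back into ``problem.params`` as the
    new starting values.  Returns the refined full parameter vector.
    """
    if not isinstance(problem, SpectraFitProblem):
        raise TypeError("refine_start operates on spectra fit problems")
    params = problem.params
    free = [i for i, p in enumerate(params) if not p.fixed]
    theta0 = problem.initial_theta()
    eps = 1e-12

    def residuals(x: np.ndarray) -> np.ndarray:
        theta = theta0.copy()
        theta[free] = x
        out = []
        for g, s in enumerate(problem.spectra):
            out.append((s.intensity - problem.expected(g, theta)) / s.uncertainty)
        return np.concatenate(out)

    lo = np.array([params[i].low for i in free])
    hi = np.array([params[i].high for i in free])
    x0 = np.clip(theta0[free], lo + eps, hi - eps)
    result = least_squares(
        residuals, x0, bounds=(lo, hi), max_nfev=max_nfev, method="trf"
    )
    theta = theta0.copy()
    theta[free] = result.x
    for i in free:
        params[i].init = float(np.clip(theta[i], params[i].low, params[i].high))
    return theta


# ---------------------------------------------------------------------------
# chi2 PDFs and model comparison


@dataclass(frozen=True)
class Chi2Pdf:
    """Normalized histogram of the chain's chi-squared values."""

    edges: np.ndarray
    density: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def area(self) -> float:
        return float(np.sum(self.density * np.diff(self.edges)))

    @property
    def mode(self) -> float:
        return float(self.centers[int(np.argmax(self.density))])

    @property
    def center_of_mass(self) -> float:
        w = self.density * np.diff(self.edges)
        return float(np.sum(self.centers * w) / np.sum(w))


def chi2_pdf(chain: ChainResult, n_bins: int = 80) -> Chi2Pdf:
    """Probability distribution function of the retained chi-squared trace."""
    if chain.chi2_trace.size == 0:
        raise ValueError("chain is empty")
    trace = chain.chi2_trace
    lo, hi = float(trace.min()), float(trace.max())
    if hi == lo:  # degenerate chain: one occupied bin
        hi = lo + max(abs(lo) * 1e-12, 1e-12)
    density, edges = np.histogram(trace, bins=n_bins, range=(lo, hi), density=True)
    return Chi2Pdf(edges=edges, density=density)


@dataclass(frozen=True)
class ModelComparison:
    mode_a: float
    mode_b: float
    com_a: float
    com_b: float
    preferred: Literal["a", "b", "inconclusive"]


def compare_models(pdf_a: Chi2Pdf, pdf_b: Chi2Pdf) -> ModelComparison:
    """Prefer the model whose chi2 PDF has both the smaller mode and the
    smaller centre of mass; disagreement between the two statistics (or
    exact ties) is reported as inconclusive."""
    ma, mb = pdf_a.mode, pdf_b.mode
    ca, cb = pdf_a.center_of_mass, pdf_b.center_of_mass
    if ma < mb and ca < cb:
        preferred = "a"
    elif mb < ma and cb < ca:
        preferred = "b"
    else:
        preferred = "inconclusive"
    return ModelComparison(mode_a=ma, mode_b=mb, com_a=ca, com_b=cb, preferred=preferred)


# ---------------------------------------------------------------------------
# fit-problem factories


def _baseline_guess(spec: Spectrum) -> tuple[float, float]:
    """Amplitude (integrated counts) and flat background (counts/bin) guesses."""
    n = spec.grid.n_bins
    edge = max(5, n // 10)
    c0 = float(
        np.median(np.concatenate([spec.intensity[:edge], spec.intensity[-edge:]]))
    )
    total = float(spec.intensity.sum())
    a0 = max(total - c0 * n, 0.05 * total)
    return a0, c0


def _width_param(name: str, q: int, init: float) -> Param:
    return Param(name, init, 1e-6, 30.0, max(0.2 * init, 0.01), q_index=q)


def lipid_fit_problem(
    spectra: Sequence[Spectrum],
    kernel: ResolutionKernel,
    mode: Mode,
    global_transport: bool = False,
) -> SpectraFitProblem:
    """Single-population lipid fit: per Q free amplitude a, EISF A_s, local
    width Gamma_s, long-range width and flat background.

    With ``global_transport=True`` the per-Q long-range widths are replaced
    by a single transport parameter obeying the dispersion relation
    (Gamma = hbar D Q^2 in diffusion mode, sigma = hbar v0 Q in flow mode;
    the parameter ``transport`` is D in A^2/ns or v0 in A/ns).  The per-Q
    width route with a posteriori regression is the reference behaviour;
    the global mode is a consistency option.
    """
    from .constants import HBAR_UEV_NS

    params: list[Param] = []
    if global_transport:
        params.append(Param("transport", 1.0, 1e-6, 100.0, 0.05))
    idx: list[dict[str, int]] = []
    for q, s in enumerate(spectra):
        a0, c0 = _baseline_guess(s)
        base = len(params)
        params += [
            Param(f"a[{q}]", a0, 0.0, 20.0 * a0, 0.01 * a0, q_index=q),
            Param(f"A_s[{q}]", 0.7, 0.0, 1.0, 0.03, q_index=q),
            _width_param(f"Gamma_s[{q}]", q, 3.0),
        ]
        if not global_transport:
            params.append(_width_param(f"width[{q}]", q, 0.3))
        params.append(
            Param(f"c[{q}]", c0, 0.0, 20.0 * c0 + 1.0, 0.05 * c0 + 0.05, q_index=q)
        )
        keys = ["a", "A_s", "Gamma_s"] + ([] if global_transport else ["w"]) + ["c"]
        idx.append({k: base + j for j, k in enumerate(keys)})
    bw = kernel.grid.bin_width
    Qs = [s.Q for s in spectra]

    def expected(q: int, theta: np.ndarray) -> np.ndarray:
        m = idx[q]
        if global_transport:
            if mode == "diffusion":
                width = HBAR_UEV_NS * theta[0] * Qs[q] ** 2
            else:
                width = HBAR_UEV_NS * theta[0] * Qs[q]
        else:
            width = theta[m["w"]]
        lipid = LipidParams(
            A_s=theta[m["A_s"]],
            Gamma_s=theta[m["Gamma_s"]],
            long_range=width,
            a=theta[m["a"]],
        )
        model = build_lipid_model(lipid, mode)
        return convolve(model, kernel) * bw + theta[m["c"]]

    return SpectraFitProblem(spectra, kernel, params, expected)


def membrane_fit_problem(
    spectra: Sequence[Spectrum],
    kernel: ResolutionKernel,
    mode: Mode,
    p_center: float,
    p_halfwidth: float = 0.15,
) -> SpectraFitProblem:
    """Two-component (lipid + peptide) fit.

    The peptide spectral weight ``p`` is a global parameter bounded to
    ``p_center +- p_halfwidth`` around its contrast-calculated value; the
    peptide long-range term is always Lorentzian (diffusive peptide), the
    lipid long-range term follows ``mode``.
    """
    params: list[Param] = [
        Param(
            "p",
            p_center,
            max(0.0, p_center - p_halfwidth),
            min(1.0, p_center + p_halfwidth),
            0.02,
        )
    ]
    idx: list[dict[str, int]] = []
    for q, s in enumerate(spectra):
        a0, c0 = _baseline_guess(s)
        base = len(params)
        params += [
            Param(f"a[{q}]", a0, 0.0, 20.0 * a0, 0.01 * a0, q_index=q),
            Param(f"A_s[{q}]", 0.7, 0.0, 1.0, 0.03, q_index=q),
            _width_param(f"Gamma_s[{q}]", q, 3.0),
            _width_param(f"width[{q}]", q, 0.3),
            Param(f"b[{q}]", a0, 0.0, 20.0 * a0, 0.01 * a0, q_index=q),
            Param(f"B_s[{q}]", 0.7, 0.0, 1.0, 0.03, q_index=q),
            _width_param(f"Gamma_s_pep[{q}]", q, 3.0),
            _width_param(f"width_pep[{q}]", q, 0.05),
            Param(f"c[{q}]", c0, 0.0, 20.0 * c0 + 1.0, 0.05 * c0 + 0.05, q_index=q),
        ]
        keys = ["a", "A_s", "Gamma_s", "w", "b", "B_s", "Gs_pep", "w_pep", "c"]
        idx.append({k: base + j for j, k in enumerate(keys)})
    bw = kernel.grid.bin_width

    def expected(q: int, theta: np.ndarray) -> np.ndarray:
        m = idx[q]
        lipid = LipidParams(
            A_s=theta[m["A_s"]],
            Gamma_s=theta[m["Gamma_s"]],
            long_range=theta[m["w"]],
            a=theta[m["a"]],
        )
        peptide = PeptideParams(
            B_s=theta[m["B_s"]],
            Gamma_s_peptide=theta[m["Gs_pep"]],
            Gamma_peptide=theta[m["w_pep"]],
            b=theta[m["b"]],
            p=theta[0],
        )
        model = build_membrane_model(lipid, peptide, mode)
        return convolve(model, kernel) * bw + theta[m["c"]]

    return SpectraFitProblem(spectra, kernel, params, expected)


def membrane_contrast_pair_problem(
    spectra_sets: Sequence[Sequence[Spectrum]],
    kernel: ResolutionKernel,
    mode: Mode,
    p_centers: Sequence[float],
    p_halfwidth: float = 0.15,
) -> SpectraFitProblem:
    """Joint two-component fit across scattering contrasts.

    The same vesicle dynamics measured at different H/D contrasts (e.g.
    protonated lipid, p ~ 0.2, and chain-deuterated lipid, p ~ 0.5) share all
    dynamical parameters per Q (EISFs, local widths, long-range widths) while
    amplitudes, backgrounds and the spectral weight p are per contrast.  The
    differing lipid/peptide mixing ratios are what make the two overlapping
    components identifiable -- the point of contrast variation.

    ``spectra_sets[k][q]`` must be measured at the same Q for every contrast
    ``k``; groups are ordered contrast-major.
    """
    n_sets = len(spectra_sets)
    if n_sets < 2 or len(p_centers) != n_sets:
        raise ValueError("need >= 2 contrasts with one p_center each")
    nq = len(spectra_sets[0])
    for spectra in spectra_sets:
        if len(spectra) != nq:
            raise ValueError("all contrasts must share the Q set")
    params: list[Param] = []
    ip: list[int] = []
    for k, pc in enumerate(p_centers):
        ip.append(len(params))
        params.append(
            Param(
                f"p[{k}]",
                pc,
                max(0.0, pc - p_halfwidth),
                min(1.0, pc + p_halfwidth),
                0.02,
                groups=tuple(range(k * nq, (k + 1) * nq)),
            )
        )
    shared_idx: list[dict[str, int]] = []
    amp_idx: list[list[dict[str, int]]] = [[] for _ in range(n_sets)]
    for q in range(nq):
        both = tuple(k * nq + q for k in range(n_sets))
        base = len(params)
        params += [
            Param(f"A_s[{q}]", 0.7, 0.0, 1.0, 0.03, groups=both),
            Param(f"Gamma_s[{q}]", 3.0, 1e-6, 30.0, 0.5, groups=both),
            Param(f"width[{q}]", 0.3, 1e-6, 30.0, 0.05, groups=both),
            Param(f"B_s[{q}]", 0.7, 0.0, 1.0, 0.03, groups=both),
            Param(f"Gamma_s_pep[{q}]", 3.0, 1e-6, 30.0, 0.5, groups=both),
            Param(f"width_pep[{q}]", 0.05, 1e-6, 30.0, 0.01, groups=both),
        ]
        keys = ["A_s", "Gamma_s", "w", "B_s", "Gs_pep", "w_pep"]
        shared_idx.append({kk: base + j for j, kk in enumerate(keys)})
        for k in range(n_sets):
            s = spectra_sets[k][q]
            a0, c0 = _baseline_guess(s)
            g = k * nq + q
            base = len(params)
            params += [
                Param(f"a[{k}][{q}]", a0, 0.0, 20.0 * a0, 0.01 * a0, groups=(g,)),
                Param(f"b[{k}][{q}]", a0, 0.0, 20.0 * a0, 0.01 * a0, groups=(g,)),
                Param(
                    f"c[{k}][{q}]",
                    c0,
                    0.0,
                    20.0 * c0 + 1.0,
                    0.05 * c0 + 0.05,
                    groups=(g,),
                ),
            ]
            amp_idx[k].append({kk: base + j for j, kk in enumerate(["a", "b", "c"])})
    flat = [s for spectra in spectra_sets for s in spectra]
    bw = kernel.grid.bin_width

    def expected(g: int, theta: np.ndarray) -> np.ndarray:
        k, q = divmod(g, nq)
        sh = shared_idx[q]
        am = amp_idx[k][q]
        lipid = LipidParams(
            A_s=theta[sh["A_s"]],
            Gamma_s=theta[sh["Gamma_s"]],
            long_range=theta[sh["w"]],
            a=theta[am["a"]],
        )
        peptide = PeptideParams(
            B_s=theta[sh["B_s"]],
            Gamma_s_peptide=theta[sh["Gs_pep"]],
            Gamma_peptide=theta[sh["w_pep"]],
            b=theta[am["b"]],
            p=theta[ip[k]],
        )
        model = build_membrane_model(lipid, peptide, mode)
        return convolve(model, kernel) * bw + theta[am["c"]]

    return SpectraFitProblem(flat, kernel, params, expected)


def extended_fit_problem(
    spectra: Sequence[Spectrum],
    kernel: ResolutionKernel,
    mode: Mode,
    width_1: Sequence[float],
    peptide_fixed: Sequence[dict],
    p: float,
) -> SpectraFitProblem:
    """Two-population lipid fit.

    ``width_1`` fixes the free-lipid long-range width per Q (taken from the
    pure-lipid analysis); ``peptide_fixed`` supplies per-Q dicts with keys
    ``b``, ``B_s``, ``Gamma_s_peptide``, ``Gamma_peptide`` (from the previous
    two-component fit), and ``p`` is the fixed peptide spectral weight.  The
    peptide *dynamics* (EISF and widths) and ``p`` are held fixed; the
    peptide amplitude ``b(Q)``, like ``a(Q)``, remains a free per-Q scale
    (initialised from ``peptide_fixed``).  Free parameters: the global
    free-lipid fraction ``l``, and per Q the slowed width, amplitudes, lipid
    EISF, lipid local width and background.
    """
    if len(width_1) != len(spectra) or len(peptide_fixed) != len(spectra):
        raise ValueError("width_1 and peptide_fixed must have one entry per Q")
    params: list[Param] = [Param("l", 0.5, 0.0, 1.0, 0.03)]
    idx: list[dict[str, int]] = []
    for q, s in enumerate(spectra):
        a0, c0 = _baseline_guess(s)
        b0 = float(peptide_fixed[q]["b"])
        base = len(params)
        params += [
            Param(f"a[{q}]", a0, 0.0, 20.0 * a0, 0.01 * a0, q_index=q),
            Param(f"A_s[{q}]", 0.7, 0.0, 1.0, 0.03, q_index=q),
            _width_param(f"Gamma_s[{q}]", q, 3.0),
            _width_param(f"width2[{q}]", q, 0.5 * width_1[q]),
            Param(f"b[{q}]", b0, 0.0, 20.0 * max(b0, a0), 0.01 * max(b0, a0), q_index=q),
            Param(f"c[{q}]", c0, 0.0, 20.0 * c0 + 1.0, 0.05 * c0 + 0.05, q_index=q),
        ]
        keys = ["a", "A_s", "Gamma_s", "w2", "b", "c"]
        idx.append({k: base + j for j, k in enumerate(keys)})
    bw = kernel.grid.bin_width
    w1 = [float(w) for w in width_1]
    pep = [dict(d) for d in peptide_fixed]

    def expected(q: int, theta: np.ndarray) -> np.ndarray:
        m = idx[q]
        lipid = LipidParams(
            A_s=theta[m["A_s"]],
            Gamma_s=theta[m["Gamma_s"]],
            long_range=w1[q],  # placeholder; split handled by ExtendedLipidParams
            a=theta[m["a"]],
        )
        peptide = PeptideParams(
            B_s=pep[q]["B_s"],
            Gamma_s_peptide=pep[q]["Gamma_s_peptide"],
            Gamma_peptide=pep[q]["Gamma_peptide"],
            b=theta[m["b"]],
            p=p,
        )
        ext = ExtendedLipidParams(l=theta[0], width_1=w1[q], width_2=theta[m["w2"]])
        model = build_extended_model(lipid, peptide, ext, mode)
        return convolve(model, kernel) * bw + theta[m["c"]]

    return SpectraFitProblem(spectra, kernel, params, expected)
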