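"""End-to-end analysis workflows: generate -> fit -> extract.

These functions tie the synthetic instrument model, the adaptive-Metropolis
fitter and the dispersion regressions into the complete analyses: recovery of
the lipid diffusion coefficient or flow velocity, recovery of the peptide
diffusion coefficient from two-component spectra, the two-population fit of
the influenced lipid fraction, and the Lorentzian-vs-Gaussian model ranking
via chi-squared PDFs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .fitting import (
    ChainResult,
    Chi2Pdf,
    SpectraFitProblem,
    chi2_pdf,
    compare_models,
    extended_fit_problem,
    lipid_fit_problem,
    membrane_fit_problem,
    refine_start,
    run_mcmc,
)
from .instrument import ResolutionKernel, Spectrum, generate_dataset
from .io import RunConfig, write_spectrum
from .models import Mode, gamma_from_D
from .transport import DispersionData, fit_diffusion, fit_velocity

__all__ = [
    "FitResult",
    "fit_dataset",
    "recover_pure_lipid",
    "recover_membrane",
    "recover_peptide_two_contrast",
    "recover_influenced_fraction",
    "model_preference",
    "run_pipeline",
]


@dataclass
class FitResult:
    """Joint MCMC fit of one dataset plus posterior-summary helpers."""

    problem: SpectraFitProblem
    chain: ChainResult
    mode: Mode
    model: str

    @property
    def Q(self) -> np.ndarray:
        return np.array([s.Q for s in self.problem.spectra])

    def posterior(self, name: str) -> tuple[float, float]:
        return self.chain.mean(name), self.chain.std(name)

    def dispersion(self, prefix: str = "width") -> DispersionData:
        """Posterior means/sds of the per-Q widths named ``prefix[q]``."""
        means, sds = [], []
        for q in range(len(self.problem.spectra)):
            m, s = self.posterior(f"{prefix}[{q}]")
            means.append(m)
            sds.append(s)
        return DispersionData(
            Q=self.Q, width=np.array(means), width_err=np.array(sds)
        )

    def pdf(self, n_bins: int = 80) -> Chi2Pdf:
        return chi2_pdf(self.chain, n_bins)

    def reduced_chi2(self) -> float:
        n_data = sum(s.grid.n_bins for s in self.problem.spectra)
        n_free = sum(not p.fixed for p in self.problem.params)
        _, best = self.chain.best()
        return best / max(n_data - n_free, 1)


def fit_dataset(
    spectra: Sequence[Spectrum],
    kernel: ResolutionKernel,
    model: Literal["lipid", "membrane", "extended"] = "lipid",
    mode: Mode = "diffusion",
    cycles: int = 100_000,
    adapt_every: int | None = None,
    target_accept: float = 0.66,
    seed: int | None = None,
    thin: int = 1,
    optimize_start: bool = True,
    p_center: float | None = None,
    p_halfwidth: float = 0.15,
    width_1: Sequence[float] | None = None,
    peptide_fixed: Sequence[dict] | None = None,
) -> FitResult:
    """Build the fit problem for ``model``, optionally refine the start by
    weighted least squares, and run the adaptive Metropolis chain."""
    if adapt_every is None:
        adapt_every = max(cycles // 10, 1)
    if model == "lipid":
        problem = lipid_fit_problem(spectra, kernel, mode)
    elif model == "membrane":
        if p_center is None:
            raise ValueError("membrane fits need the contrast-calculated p_center")
        problem = membrane_fit_problem(spectra, kernel, mode, p_center, p_halfwidth)
    elif model == "extended":
        if width_1 is None or peptide_fixed is None or p_center is None:
            raise ValueError(
                "extended fits need width_1, peptide_fixed and p_center"
            )
        problem = extended_fit_problem(
            spectra, kernel, mode, width_1, peptide_fixed, p_center
        )
    else:
        raise ValueError(f"unknown model {model!r}")
    if optimize_start:
        refine_start(problem)
    chain = run_mcmc(
        problem,
        cycles=cycles,
        adapt_every=adapt_every,
        target_accept=target_accept,
        seed=seed,
        thin=thin,
    )
    return FitResult(problem=problem, chain=chain, mode=mode, model=model)


def recover_pure_lipid(
    mode: Mode = "diffusion",
    seed: int = 0,
    cycles: int = 100_000,
    counts: int = 1_000_000,
    adapt_every: int | None = None,
    target_accept: float = 0.66,
    thin: int = 1,
    **generator_kwargs,
) -> dict:
    """Generate a pure-lipid dataset at the study conditions, fit it, and
    regress the widths to D (diffusion) or v0 (flow)."""
    data = generate_dataset(
        "pure_lipid", mode, counts=counts, seed=seed, **generator_kwargs
    )
    fit = fit_dataset(
        data.spectra,
        data.kernel,
        model="lipid",
        mode=mode,
        cycles=cycles,
        adapt_every=adapt_every,
        target_accept=target_accept,
        thin=thin,
        seed=seed,
    )
    disp = fit.dispersion("width")
    out = {"fit": fit, "dispersion": disp, "truth": data.truth}
    if mode == "diffusion":
        D, D_err = fit_diffusion(disp)
        out.update({"D_cm2_per_s": D, "D_err": D_err})
    else:
        v0, v0_err = fit_velocity(disp)
        out.update({"v0_m_per_s": v0, "v0_err": v0_err})
    return out


def recover_membrane(
    mode: Mode = "diffusion",
    seed: int = 0,
    cycles: int = 100_000,
    counts: int = 1_000_000,
    p_center: float = 0.2,
    adapt_every: int | None = None,
    target_accept: float = 0.66,
    thin: int = 1,
    **generator_kwargs,
) -> dict:
    """Two-component recovery: lipid transport plus the peptide diffusion
    coefficient from the same joint fit."""
    data = generate_dataset(
        "lipid_peptide",
        mode,
        counts=counts,
        seed=seed,
        p=generator_kwargs.pop("p", p_center),
        **generator_kwargs,
    )
    fit = fit_dataset(
        data.spectra,
        data.kernel,
        model="membrane",
        mode=mode,
        cycles=cycles,
        adapt_every=adapt_every,
        target_accept=target_accept,
        thin=thin,
        seed=seed,
        p_center=p_center,
    )
    disp_lip = fit.dispersion("width")
    disp_pep = fit.dispersion("width_pep")
    D_pep, D_pep_err = fit_diffusion(disp_pep)
    out = {
        "fit": fit,
        "lipid_dispersion": disp_lip,
        "peptide_dispersion": disp_pep,
        "D_peptide_cm2_per_s": D_pep,
        "D_peptide_err": D_pep_err,
        "truth": data.truth,
    }
    if mode == "diffusion":
        D, D_err = fit_diffusion(disp_lip)
        out.update({"D_lipid_cm2_per_s": D, "D_lipid_err": D_err})
    else:
        v0, v0_err = fit_velocity(disp_lip)
        out.update({"v0_lipid_m_per_s": v0, "v0_lipid_err": v0_err})
    return out


def recover_peptide_two_contrast(
    seed: int = 0,
    mode: Mode = "diffusion",
    cycles: int = 100_000,
    counts: int = 1_000_000,
    p_centers: tuple[float, float] = (0.207, 0.492),
    D_lipid: float = 8e-8,
    D_peptide: float = 0.5e-8,
    adapt_every: int | None = None,
    target_accept: float = 0.66,
    thin: int = 1,
    **generator_kwargs,
) -> dict:
    """Peptide diffusion from a joint fit of two scattering contrasts.

    Generates peptide-loaded datasets at the protonated-lipid and
    chain-deuterated-lipid contrasts (same dynamics, peptide spectral weights
    ``p_centers``), fits them jointly with shared dynamical parameters, and
    regresses the shared peptide widths to D_peptide.  A single contrast
    leaves the two overlapping components nearly degenerate; the pair pins
    them down.
    """
    from .fitting import membrane_contrast_pair_problem

    rng = np.random.default_rng(seed)
    sets = []
    kernel = None
    for p in p_centers:
        data = generate_dataset(
            "lipid_peptide",
            mode,
            D_lipid=D_lipid,
            D_peptide=D_peptide,
            p=p,
            counts=counts,
            seed=int(rng.integers(2**31 - 1)),
            **generator_kwargs,
        )
        sets.append(data.spectra)
        kernel = data.kernel
    problem = membrane_contrast_pair_problem(
        sets, kernel, mode, p_centers=list(p_centers)
    )
    refine_start(problem)
    chain = run_mcmc(
        problem,
        cycles=cycles,
        adapt_every=adapt_every or max(cycles // 10, 1),
        target_accept=target_accept,
        thin=thin,
        seed=seed,
    )
    fit = FitResult(problem=problem, chain=chain, mode=mode, model="membrane_pair")
    Q = np.array([s.Q for s in sets[0]])
    means, sds = [], []
    for q in range(len(Q)):
        means.append(chain.mean(f"width_pep[{q}]"))
        sds.append(chain.std(f"width_pep[{q}]"))
    disp_pep = DispersionData(Q=Q, width=np.array(means), width_err=np.array(sds))
    D_pep, D_pep_err = fit_diffusion(disp_pep)
    means, sds = [], []
    for q in range(len(Q)):
        means.append(chain.mean(f"width[{q}]"))
        sds.append(chain.std(f"width[{q}]"))
    disp_lip = DispersionData(Q=Q, width=np.array(means), width_err=np.array(sds))
    out = {
        "fit": fit,
        "peptide_dispersion": disp_pep,
        "lipid_dispersion": disp_lip,
        "D_peptide_cm2_per_s": D_pep,
        "D_peptide_err": D_pep_err,
    }
    if mode == "diffusion":
        D, err = fit_diffusion(disp_lip)
        out.update({"D_lipid_cm2_per_s": D, "D_lipid_err": err})
    else:
        v0, err = fit_velocity(disp_lip)
        out.update({"v0_lipid_m_per_s": v0, "v0_lipid_err": err})
    return out


def recover_influenced_fraction(
    seed: int = 0,
    mode: Mode = "diffusion",
    cycles: int = 100_000,
    counts: int = 1_000_000,
    D_slow: float = 8e-8,
    D_free: float = 21e-8,
    influenced_fraction: float = 0.8,
    p_centers: tuple[float, float] = (0.207, 0.492),
    adapt_every: int | None = None,
    target_accept: float = 0.66,
    thin: int = 1,
    **generator_kwargs,
) -> dict:
    """Two-stage analysis of the two-population model.

    Stage one fits the single-lipid-width two-component model jointly across
    the two scattering contrasts to pin the peptide parameters (the contrast
    pair is what makes the peptide component identifiable).  Stage two fits
    the two-population model to the protonated-contrast spectra with the
    free-lipid width held at its pure-lipid dispersion value
    (``hbar * D_free * Q^2``) and the peptide terms fixed at the stage-one
    posteriors, leaving the slowed width and the population split ``l`` free.
    Reports the influenced percentage 100 * (1 - l).
    """
    from .fitting import membrane_contrast_pair_problem

    rng = np.random.default_rng(seed)
    sets = []
    kernel = None
    for p in p_centers:
        data = generate_dataset(
            "extended",
            mode,
            D_lipid=D_slow,
            D_free=D_free,
            influenced_fraction=influenced_fraction,
            p=p,
            counts=counts,
            seed=int(rng.integers(2**31 - 1)),
            **generator_kwargs,
        )
        sets.append(data)
        kernel = data.kernel
    problem1 = membrane_contrast_pair_problem(
        [d.spectra for d in sets], kernel, mode, p_centers=list(p_centers)
    )
    refine_start(problem1)
    chain1 = run_mcmc(
        problem1,
        cycles=cycles,
        adapt_every=adapt_every or max(cycles // 10, 1),
        target_accept=target_accept,
        thin=thin,
        seed=seed,
    )
    stage1 = FitResult(
        problem=problem1, chain=chain1, mode=mode, model="membrane_pair"
    )
    spectra = sets[0].spectra  # protonated contrast carries the lipid signal
    peptide_fixed = []
    for q in range(len(spectra)):
        peptide_fixed.append(
            {
                "b": chain1.mean(f"b[0][{q}]"),
                "B_s": min(max(chain1.mean(f"B_s[{q}]"), 0.0), 1.0),
                "Gamma_s_peptide": chain1.mean(f"Gamma_s_pep[{q}]"),
                "Gamma_peptide": chain1.mean(f"width_pep[{q}]"),
            }
        )
    p_fixed = chain1.mean("p[0]")
    width_1 = [gamma_from_D(s.Q, D_free) for s in spectra]
    stage2 = fit_dataset(
        spectra,
        kernel,
        model="extended",
        mode=mode,
        cycles=cycles,
        adapt_every=adapt_every,
        target_accept=target_accept,
        thin=thin,
        seed=seed + 1,
        p_center=p_fixed,
        width_1=width_1,
        peptide_fixed=peptide_fixed,
    )
    l_mean, l_sd = stage2.posterior("l")
    return {
        "fit": stage2,
        "stage1": stage1,
        "l": l_mean,
        "l_err": l_sd,
        "influenced_percent": 100.0 * (1.0 - l_mean),
        "truth": sets[0].truth,
    }


def model_preference(
    seed: int = 0,
    generating_mode: Mode = "diffusion",
    cycles: int = 100_000,
    counts: int = 1_000_000,
    adapt_every: int | None = None,
    target_accept: float = 0.66,
    thin: int = 1,
    **generator_kwargs,
) -> dict:
    """Fit both long-range models to one pure-lipid dataset and rank them by
    the mode and centre of mass of their chi-squared PDFs."""
    data = generate_dataset(
        "pure_lipid", generating_mode, counts=counts, seed=seed, **generator_kwargs
    )
    fits = {}
    for mode in ("diffusion", "flow"):
        fits[mode] = fit_dataset(
            data.spectra,
            data.kernel,
            model="lipid",
            mode=mode,
            cycles=cycles,
            adapt_every=adapt_every,
            target_accept=target_accept,
            thin=thin,
            seed=seed,
        )
    comparison = compare_models(fits["diffusion"].pdf(), fits["flow"].pdf())
    preferred = {"a": "diffusion", "b": "flow", "inconclusive": "inconclusive"}[
        comparison.preferred
    ]
    return {"comparison": comparison, "preferred": preferred, "fits": fits}


def run_pipeline(config: RunConfig) -> dict:
    """Run one configured scenario end to end and return a JSON-able report.

    Writes the generated spectra and a ``summary.json`` to
    ``config.output_dir`` when set.
    """
    common = dict(
        cycles=config.cycles,
        adapt_every=config.adapt_every,
        target_accept=config.target_accept,
        thin=config.thin,
        counts=config.counts,
        Q_set=config.Q_set,
        omega_max=config.omega_max_ueV,
        bin_width=config.bin_ueV,
        fwhm=config.resolution_fwhm_ueV,
        seed=config.seed,
    )
    report: dict = {
        "scenario": config.scenario,
        "mode": config.mode,
        "seed": config.seed,
    }
    if config.scenario == "pure_lipid":
        res = recover_pure_lipid(
            mode=config.mode,
            D_lipid=config.D_lipid_cm2_per_s,
            v0_lipid=config.v0_lipid_m_per_s,
            **common,
        )
    elif config.scenario == "lipid_peptide":
        res = recover_membrane(
            mode=config.mode,
            D_lipid=config.D_lipid_cm2_per_s,
            v0_lipid=config.v0_lipid_m_per_s,
            D_peptide=config.D_peptide_cm2_per_s,
            p_center=config.p,
            **common,
        )
    else:
        res = recover_influenced_fraction(
            mode=config.mode,
            D_slow=config.D_lipid_cm2_per_s,
            D_free=config.D_free_cm2_per_s,
            influenced_fraction=config.influenced_fraction,
            D_peptide=config.D_peptide_cm2_per_s,
            p_centers=(config.p, config.p_deuterated),
            **common,
        )
    fit: FitResult = res["fit"]
    report["reduced_chi2"] = fit.reduced_chi2()
    report["acceptance_rate"] = fit.chain.acceptance_rate
    for key in (
        "D_cm2_per_s",
        "D_err",
        "v0_m_per_s",
        "v0_err",
        "D_lipid_cm2_per_s",
        "D_lipid_err",
        "v0_lipid_m_per_s",
        "v0_lipid_err",
        "D_peptide_cm2_per_s",
        "D_peptide_err",
        "l",
        "l_err",
        "influenced_percent",
    ):
        if key in res:
            report[key] = float(res[key])

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for spec in fit.problem.spectra:
            write_spectrum(spec, out / f"spectrum_Q{spec.Q:.2f}.tsv")
        with (out / "summary.json").open("w") as fh:
            json.dump(report, fh, indent=2)
    return report
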