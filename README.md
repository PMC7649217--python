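# qensmem

Quasielastic neutron scattering (QENS) analysis of lipid and
transmembrane-peptide dynamics in model membranes.

High-resolution neutron backscattering resolves the quasielastic broadening
of the elastic line caused by molecular motions on nanosecond time and
nanometre length scales — exactly the regime of lateral lipid diffusion and
of the slow creep of transmembrane peptides. `qensmem` provides the full
analysis chain for such experiments on vesicle samples, exercised end to end
on synthetic data: forward scattering models, resolution convolution,
Bayesian model fitting with χ²-PDF model comparison, and the extraction of
transport coefficients and of the fraction of lipids whose mobility is
slowed by an embedded peptide.

## The models

The dynamic structure factor of a lipid vesicle near the elastic line is
modelled as a long-range translational term convolved with a localized slow
motion, plus a flat background *c* for motions too fast for the energy
window:

    S(Q,ω) = a(Q) · LR(ω) ⊗ [ A_s(Q) δ(ω) + (1 − A_s(Q)) L(Γ_s, ω) ] + c

where the long-range shape `LR` is either a Lorentzian `L(Γ_lipid, ω)`
(continuous diffusion, Γ_lipid = ħDQ²) or a Gaussian `G(σ_lipid, ω)`
(flow-like ballistic motion, σ_lipid = ħv₀Q), `A_s` is the elastic
incoherent structure factor of the localized motion and `a(Q)` a free
per-Q amplitude. Peptide-loaded membranes add a second component of the
same structure with spectral weight *p* (the peptide's share of the
incoherent signal, computed from hydrogen counts and cross sections), and
the two-population extension splits the lipid term into a fraction *l* of
free lipids at the pure-lipid width and 1 − *l* of slowed lipids at a fitted
width.

Fitting follows the Bayesian χ²-sampling approach used at backscattering
instruments: an adaptive single-site Metropolis walk on χ² (acceptance
exp(−Δχ²/2), proposal widths retuned toward a 0.66 acceptance ratio every
adaptation block), with competing models ranked by the mode and centre of
mass of their χ² probability distribution functions. Transport coefficients
come from origin-constrained regressions of the fitted widths (Γ vs Q²,
σ vs Q), and the influenced-lipid fraction converts to a peptide–lipid
interaction radius through a per-leaflet disc model,
r = √((A_pep + f·(N/2)·A_lip)/π).

## Worked example

```
$ python examples/fit_lipid_diffusion.py
fitted Lorentzian HWHMs (ueV) vs Q (1/A):
  Q = 0.29   Gamma = 0.1165 +- 0.0013
  Q = 0.44   Gamma = 0.2629 +- 0.0022
  Q = 0.57   Gamma = 0.4480 +- 0.0048
  Q = 0.78   Gamma = 0.8348 +- 0.0072
  Q = 0.95   Gamma = 1.2359 +- 0.0195

D = (20.83 +- 0.09) x 1e-8 cm^2/s   (generating value 21)
chi2/dof of the best fit: 1.023
```

The script simulates five spectra of a pure lipid vesicle sample
(Q = 0.29–0.95 Å⁻¹, ±30 μeV window, 0.1 μeV bins, 0.75 μeV FWHM Gaussian
resolution, Poisson noise), fits the diffusive model jointly over all Q and
regresses the widths to the apparent self-diffusion coefficient: the
generating value is recovered within a percent at these statistics.

Other examples, one per capability:

- `examples/simulate_and_reduce.py` — forward simulation plus vanadium
  normalization, background subtraction and rebinning.
- `examples/compare_long_range_models.py` — diffusive vs flow-like model
  ranking by χ² PDFs.
- `examples/peptide_descriptors_and_contrast.py` — sequence charge,
  hydrophobicity, hydrophobic moment and the H/D contrast calculation.
- `examples/influenced_fraction_and_radius.py` — two-population fit of the
  peptide-influenced lipid fraction and the disc-model interaction radius.
- `examples/msd_diffusion.py` — diffusion coefficients from mean-square
  displacements of 2D trajectories.

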