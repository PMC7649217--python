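# Methods

## Scattering models

Incoherent QENS spectra of vesicle samples are modelled per momentum
transfer Q as a sum of centred line shapes convolved with the instrument
resolution. The lipid component is a long-range translational shape —
Lorentzian `L(Γ_lipid, ω)` for continuous diffusion or Gaussian
`G(σ_lipid, ω)` for flow-like collective motion — convolved with a
localized slow motion `A_s δ(ω) + (1 − A_s) L(Γ_s, ω)`, scaled by a free
per-Q amplitude `a(Q)`. Motions too fast for the energy window enter only
as a flat constant `c`; no explicit fast Lorentzian is modelled. The
peptide component has the same structure with weight `p`, amplitude `b(Q)`,
EISF `B_s` and a Lorentzian long-range term (a transmembrane peptide spans
both leaflets and is taken to diffuse, not flow). The two-population
extension splits the lipid term into fractions `l` (free, width fixed from
the pure-lipid analysis) and `1 − l` (slowed, width fitted), sharing `A_s`
and `Γ_s`.

All model algebra is symbolic on weighted term sets: L⊗L adds HWHMs, G⊗G
adds variances, G⊗L is a Voigt profile evaluated with
`scipy.special.voigt_profile` (exact; the test suite cross-checks it
against direct-summation numerical convolution to better than 1e-4
relative). δ components are never discretized — they acquire the kernel
shape on convolution, avoiding bin-width artefacts. With a parametric
Gaussian resolution kernel the model⊗resolution convolution is therefore
fully analytic (δ→Gaussian, L→Voigt, G→wider Gaussian, Voigt→wider Voigt);
a tabulated kernel falls back to numerical convolution on a padded grid.

Units: energies and widths in μeV, Q in Å⁻¹, ħ = 0.6582119569 μeV·ns.
Transport coefficients cross the API in conventional units
(D in cm²/s = 10⁷ Å²/ns; v₀ in m/s = 10 Å/ns), with the dispersion
relations Γ = ħDQ² and σ = ħv₀Q. The amplitude `a(Q)` is treated as a free
per-Q scale (it absorbs the Debye–Waller factor, which is not modelled
separately), and the EISF is fitted freely per Q — no functional form is
assumed in fits.

## Synthetic instrument model

The generator emulates a high-resolution backscattering measurement:

| parameter | default | rationale |
| --- | --- | --- |
| resolution | Gaussian, 0.75 μeV FWHM, Q-independent | nominal backscattering resolution; a tabulated per-Q kernel is accepted for generality |
| energy window | ±30 μeV, 0.1 μeV bins | narrow backscattering dynamic range; reported binning |
| Q set | 0.29, 0.44, 0.57, 0.78, 0.95 Å⁻¹ | the three reported Q values plus two interpolated, so dispersion regressions have five supports |
| counts | 10⁶ per spectrum | high-statistics overnight run scale |
| noise | Poisson per bin, σ = √max(n,1) | counting statistics |
| lipid D | 21×10⁻⁸ cm²/s (pure), 8×10⁻⁸ (peptide-loaded) | reported values |
| lipid v₀ | 0.27 m/s (pure), 0.13 (loaded) | reported values |
| peptide D | 0.5×10⁻⁸ cm²/s | reported value; sub-resolution width |
| p | 0.207 (protonated) / 0.492 (chain-deuterated) | computed from the contrast model |
| EISF | sphere model [3 j₁(QR)/(QR)]², R = 2 Å | generation only; fits never assume the form |
| Γ_s | 5 μeV (lipid and peptide local motions) | a localized width well inside the window but clearly broader than the long-range terms |
| background c | 0.002 μeV⁻¹ per unit model weight (~10% of counts) | keeps wing bins at O(10²) counts so Gaussian χ² is a good approximation |

All randomness flows from one seed through `numpy.random.default_rng`.
2D Brownian trajectories (per-axis step σ = √(2DΔt)) stand in for MD
centre-of-mass data in the MSD analysis; they are unwrapped by construction
and contain no interactions, crossing events or sub-diffusive regimes.

What passing recovery tests therefore show is that the *analysis chain* is
unbiased and correctly calibrated under ideal counting statistics and an
exactly known resolution; they do not probe resolution-function error,
multiple scattering, absorption, coherent contamination or non-Gaussian
instrument line shapes, which real reductions must face.

## Fitting

The sampler is a single-site random-walk Metropolis on χ² = Σ((data −
model)/σ)²: uniform priors inside finite bounds, acceptance probability
exp(−Δχ²/2), one parameter proposed per cycle in round-robin order. Every
`adapt_every` cycles (default: cycles/10) each parameter's proposal width
is rescaled by `(rate/0.66)^0.5` with a Laplace-smoothed acceptance rate,
clipped to a factor 5 per block; the reference configuration is 10⁶ cycles
with 10⁵-cycle blocks, and the test/acceptance scale is 10⁵ cycles — at
10⁶ counts per spectrum the posteriors are narrow enough that the shorter
chains already resolve them. Burn-in discards one adaptation block. Chains
start from a bounded weighted least-squares pre-fit (`scipy.optimize.
least_squares`), standard practice that removes the transient without
affecting the stationary distribution. All Q slices are fitted jointly
with per-Q parameters; per-Q moves only re-evaluate the affected spectrum.

Default bounds: widths (10⁻⁶, 30] μeV, EISFs [0, 1], amplitudes and
backgrounds [0, 20× their data-derived guesses], p within ±0.15 of its
contrast-computed value. Model comparison histograms the retained χ² trace
(normalized to unit area) and prefers the model whose PDF has both the
smaller mode and the smaller centre of mass; disagreement or exact ties are
reported as inconclusive. Degenerate (constant-χ²) chains produce a single
occupied bin. A chain that rejects every proposal for a full adaptation
block raises a diagnostic error rather than returning silently.

Transport coefficients are extracted after fitting by error-weighted
regression of the per-Q posterior widths through the origin (Γ(0) = σ(0) =
0 physically; an intercept option exists for diagnostics only). A
global-D parametrization is available as an option but the per-Q-then-
regress route is the reference behaviour.

### Identifiability and the contrast pair

With a single dataset the two-component model is nearly degenerate when the
lipid and peptide components share their localized-motion structure: the
fit can trade peptide width against the narrow lipid term with essentially
no χ² penalty, biasing the sub-resolution peptide width upward. This is
the physical reason the experiment uses contrast variation. The
`membrane_contrast_pair_problem` fits the protonated (p ≈ 0.21) and
chain-deuterated (p ≈ 0.49) datasets jointly with all dynamical parameters
shared per Q and only amplitudes, backgrounds and p per contrast; the
differing mixing ratios make the decomposition well-posed, and the peptide
diffusion coefficient is then recoverable to within a factor of two despite
its width lying far below the resolution.

The two-population analysis proceeds in two stages mirroring this logic:
stage one pins the peptide dynamics with the contrast-pair fit; stage two
fits the population split to the protonated data with the free-lipid width
fixed at ħD_free Q² and the peptide EISF/widths/weight fixed at the
stage-one posteriors. The peptide amplitude `b(Q)` stays free in stage two:
it is a per-Q scale factor like `a(Q)`, not a dynamics parameter, and
fixing it would propagate stage one's deliberate single-width lipid
approximation into the recovered fraction.

## Sequence and contrast model

Net charge is (#K + #R) − (#D + #E) with histidine neutral and termini
ignored; mean hydrophobicity is the arithmetic mean of Fauchère–Pliska
residue values; the hydrophobic moment is the Eisenberg vector sum per
residue at 100° helical twist. Hydrogen counts use standard peptide-bond
residue formulas plus two terminal hydrogens. The contrast model weights
H/D counts by incoherent cross sections (σ_H = 80.27 b, σ_D = 2.05 b),
neglecting all other nuclei, with lipid compositions 72 H (protonated
DMPC) and 18 H + 54 D (chain-deuterated). Labile-hydrogen exchange with
the D₂O buffer is off by default — counting all covalent hydrogens
reproduces both measured contrast shares — but an exchange flag
(backbone amides plus labile side-chain hydrogens) is provided.

## Interaction geometry

The influenced-lipid fraction f = 1 − l converts to an interaction radius
with a per-leaflet disc model: the peptide spans both leaflets, so its N
neighbouring lipids split evenly between monolayers and the influenced disc
in one leaflet has area A_pep + f·(N/2)·A_lip, giving r = √(area/π). At
6 mol% peptide, N = (100 − 6)/6 ≈ 15.7. Whether a whole-bilayer or
per-leaflet bookkeeping is more appropriate is genuinely open; the
per-leaflet convention is adopted and stated explicitly.

## MSD analysis

MSD curves are time- and ensemble-averaged over all (overlapping) origins;
the diffusion coefficient is the 2–5 ns slope divided by 2·dim (the window
where ballistic and cage transients have decayed in membrane systems).
Long trajectories are split into 60 ns intervals — consecutive windows
share their boundary frame so every displacement step is used exactly once
— for independent estimates. No periodic-boundary unwrapping is performed;
external data must be pre-unwrapped.

## Numerical choices and limitations

- Rebinning uses a nearest-edge convention when the target step is not a
  multiple of the native width; counts are conserved exactly and
  uncertainties combined in quadrature. Negative post-subtraction bins are
  retained to keep χ² unbiased.
- Uncertainties σ = √max(n,1) make χ² a Gaussian approximation to the
  Poisson likelihood; the default background level keeps wing counts high
  enough that the bias is negligible (verified by χ²/dof ≈ 1 tests).
- The analytic-convolution fast path exploits the symmetry of centred
  models on symmetric grids (half-grid evaluation); asymmetric grids take
  the general path.
- The scaled-down problem sizes used throughout testing are 5 Q points,
  10⁶ counts per spectrum and 10⁵ MCMC cycles; the acceptance script uses
  the same sizes and reports them alongside each value.
- Out of scope: absorption and empty-can corrections, multiple scattering,
  coherent effects, Doppler/detector simulation, MD force-field work, and
  reading MD-native trajectory formats.
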