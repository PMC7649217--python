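"""Physical constants and unit conversions.

Internal unit system: energies/widths in ueV, momentum transfer Q in 1/Angstrom,
time in ns, length in Angstrom.  Transport coefficients cross the API boundary in
the units they are conventionally reported in (D in cm^2/s, v0 in m/s).
"""

#: Reduced Planck constant in ueV * ns.
HBAR_UEV_NS = 0.6582119569

#: 1 cm^2/s expressed in A^2/ns.
CM2_PER_S_TO_A2_PER_NS = 1.0e7

#: 1 m/s expressed in A/ns.
M_PER_S_TO_A_PER_NS = 10.0

#: FWHM of a Gaussian divided by its standard deviation: sqrt(8 ln 2).
FWHM_PER_SIGMA = 2.3548200450309493

#: Incoherent neutron scattering cross sections, barn.
SIGMA_INC_H = 80.27
SIGMA_INC_D = 2.05
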