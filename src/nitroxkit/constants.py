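"""Physical constants and unit-conversion factors.

All vibrational energies in the package are expressed in wavenumbers
(cm^-1), angles in degrees at every public interface, moments of inertia
in amu*Angstrom^2, and hyperfine couplings in MHz (or Gauss where the
user asks for them).
"""

#: Boltzmann constant in cm^-1 per Kelvin.
KB_CM1_PER_K = 0.6950348

#: hbar^2 / (2 * amu * Angstrom^2) expressed in cm^-1.  The kinetic-energy
#: prefactor of an angular Hamiltonian is this value divided by the effective
#: inertia in amu*Angstrom^2 (with the angle measured in radians).
HBAR2_OVER_2_CM1_AMU_A2 = 16.8576292

#: Conversion from electron spin density at the 14N nucleus to the isotropic
#: hyperfine coupling constant, in MHz per atomic unit of spin density.
SPIN_DENSITY_TO_MHZ = 323.13

#: Same conversion but producing the coupling in Gauss.
SPIN_DENSITY_TO_GAUSS = 115.3

#: Recommended scaling factors for harmonic NO-stretch frequencies.
HARMONIC_SCALING = {"B3": 0.976, "B2": 0.980}

#: Constant anharmonic correction (cm^-1) subtracted from the B2 harmonic
#: NO-stretch frequency in the cheapest composite scheme.
CONSTANT_ANHARMONIC_SHIFT = 30.0
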