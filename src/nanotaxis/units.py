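"""Package-wide unit conventions and physical constants.

Everything in this package uses the GROMACS-style unit system:
length nm, time ps, energy kJ mol^-1, mass amu, charge e, temperature K.
Velocities are nm ps^-1 and forces kJ mol^-1 nm^-1.
"""

#: Boltzmann constant, kJ mol^-1 K^-1 (CODATA, molar).
KB = 0.00831446261815324

#: Coulomb prefactor 1/(4 pi eps0), kJ mol^-1 nm e^-2.
F_COULOMB = 138.935458


def kbt(temperature: float) -> float:
    """Thermal energy k_B*T in kJ mol^-1 at the given temperature in K."""
    return KB * temperature
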