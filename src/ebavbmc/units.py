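"""Unit system and physical constants.

The package works in the conventional units of Vashishta-form force
fields: lengths in Angstrom, energies in eV, temperature in Kelvin.
Charges are in elementary charges; the Coulomb prefactor converts
``Z_i Z_j / r`` to eV when ``r`` is in Angstrom.
"""

#: Boltzmann constant, eV / K.
KB_EV = 8.617333262e-5

#: Coulomb constant e^2 / (4 pi eps0), eV * Angstrom.
COULOMB_EV_A = 14.399645

#: Boltzmann constant, J / K (SI, used by the independent unit checks).
KB_SI = 1.380649e-23

#: Avogadro constant, 1 / mol.
N_AVOGADRO = 6.02214076e23

#: Molar mass of water, g / mol.
WATER_MOLAR_MASS = 18.02


def beta_from_temperature(T: float) -> float:
    """Return 1 / (k_B T) in 1/eV for a temperature in K."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return 1.0 / (KB_EV * T)


def number_density_from_mass_density(rho_mass_g_cm3: float) -> float:
    """Convert a mass density in g/cm^3 to a molecular number density in 1/A^3."""
    # g/cm^3 -> molecules/cm^3 -> molecules/A^3 (1 cm = 1e8 A)
    return rho_mass_g_cm3 / WATER_MOLAR_MASS * N_AVOGADRO * 1e-24


def mass_density_from_number_density(rho_num_A3: float) -> float:
    """Convert a molecular number density in 1/A^3 to a mass density in kg/m^3."""
    # molecules/A^3 -> mol/m^3 -> kg/m^3 (1 A^3 = 1e-30 m^3)
    return rho_num_A3 * 1e30 / N_AVOGADRO * WATER_MOLAR_MASS * 1e-3
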