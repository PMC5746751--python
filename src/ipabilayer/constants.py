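"""Physical constants and unit conversions used across the package.

Internal unit conventions: lengths in nm, times in ps, angles in degrees at
API boundaries, molar energies in J/mol.  The area expansion modulus is
reported in mN/m, the molecular tilt modulus in J/mol/deg^2, and splay moduli
and the effective bending rigidity in k_B*T (dimensionless multiples of the
thermal energy), matching the conventions of the bilayer literature.
"""

import math

#: Boltzmann constant, J/K (CODATA 2018, exact).
KB = 1.380649e-23
#: Avogadro constant, 1/mol (CODATA 2018, exact).
NA = 6.02214076e23
#: Molar gas constant, J/(mol K).
R = KB * NA

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 298.0

_DEG2RAD = math.pi / 180.0


def rt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Molar thermal energy R*T in J/mol."""
    return R * temperature


def kbt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in J."""
    return KB * temperature


def ka_to_mN_per_m(ka_J_per_nm2: float) -> float:
    """Convert an area modulus from J/nm^2 to mN/m.

    1 J/nm^2 = 1e18 J/m^2 = 1e18 N/m = 1e21 mN/m.
    """
    return ka_J_per_nm2 * 1.0e21


def molar_deg2_to_kbt_rad2(
    chi_J_per_mol_deg2: float, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """Convert a quadratic modulus from J/mol/deg^2 to k_B*T/rad^2.

    Dividing a molar energy by R*T gives k_B*T units per molecule; the
    curvature picks up (180/pi)^2 going from per-deg^2 to per-rad^2.
    """
    return chi_J_per_mol_deg2 / _DEG2RAD**2 / rt(temperature)


def area_variance_for_ka(
    ka_mN_per_m: float,
    mean_area_nm2: float,
    n_per_leaflet: int,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Lateral-area variance (nm^4) implied by a target area expansion modulus.

    Inverts the fluctuation relation K_A = k_B T <A> / (N <dA^2>) so that a
    synthetic area series with this variance embeds ``ka_mN_per_m`` as ground
    truth.
    """
    if ka_mN_per_m <= 0:
        raise ValueError("target K_A must be positive")
    return kbt(temperature) * mean_area_nm2 * 1.0e21 / (n_per_leaflet * ka_mN_per_m)
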