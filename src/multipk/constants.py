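"""Physical constants and unit helpers.

Internal units: lengths in Å, energies in kcal/mol, charges in elementary
charges (e), temperature in K.  Potentials are kcal/(mol·e).
"""
from __future__ import annotations

import math

from scipy import constants as _sc

#: Coulomb constant in kcal·Å/(mol·e²):  E = COULOMB_KCAL * q1*q2 / (eps*r)
COULOMB_KCAL = 332.0636

#: Boltzmann constant in kcal/(mol·K)
KB_KCAL = _sc.k * _sc.N_A / (1000.0 * _sc.calorie)

LN10 = math.log(10.0)


def kt(temperature: float) -> float:
    """Thermal energy kT in kcal/mol."""
    return KB_KCAL * temperature


def pk_to_kcal(temperature: float) -> float:
    """Energy of one pK unit, ln(10)·kT, in kcal/mol."""
    return LN10 * kt(temperature)


def debye_kappa2(ionic_strength: float, eps_solvent: float, temperature: float) -> float:
    """Squared inverse Debye length κ² in Å⁻² for a 1:1 electrolyte.

    ``ionic_strength`` is in mol/L.  κ² = 2·N_A·e²·I / (ε₀·ε_s·k_B·T),
    converted from m⁻² to Å⁻².
    """
    if ionic_strength <= 0.0:
        return 0.0
    i_si = 1000.0 * ionic_strength  # mol/m^3
    kappa2_m2 = (2.0 * _sc.N_A * _sc.e**2 * i_si) / (
        _sc.epsilon_0 * eps_solvent * _sc.k * temperature
    )
    return kappa2_m2 * 1e-20
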