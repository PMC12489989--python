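"""Physical constants and unit conversions.

Gaussian units are used internally: lengths in Å, wavevectors in Å⁻¹,
charges in units of the elementary charge e, and electrostatic potential in
e/Å.  The single fixed energy scale is

    e² = 332.06 kcal mol⁻¹ Å,

so a potential of 1 e/Å corresponds to 332.06 kcal/mol per unit charge.
Converters to mV and k_BT/e live here and are applied only at the I/O
boundary; the solver itself never mixes unit systems.
"""

from __future__ import annotations

# e^2 in kcal mol^-1 Å (Gaussian units)
E2_KCAL_MOL_A = 332.06

# k_B T at 300 K in kcal/mol
KBT_300_KCAL_MOL = 0.5961

# Boltzmann constant in kcal mol^-1 K^-1 (consistent with the above)
KB_KCAL_MOL_K = KBT_300_KCAL_MOL / 300.0

# 1 eV in kcal/mol: converts kcal/mol per e into volts
EV_KCAL_MOL = 23.060548

# number density (Å^-3) of a 1 mol/L solution
MOLAR_TO_PER_A3 = 6.02214076e-4

# 1 μC/cm² expressed in e/Å²
UC_CM2_TO_E_A2 = 1e-6 / 1.602176634e-19 / 1e16

# potential conversion factors from internal e/Å
MV_PER_E_A = E2_KCAL_MOL_A / EV_KCAL_MOL * 1000.0   # ≈ 14400 mV


def potential_to_mV(phi_e_per_A):
    """Convert a potential from internal e/Å units to millivolts."""
    return phi_e_per_A * MV_PER_E_A


def potential_to_kBT_e(phi_e_per_A, temperature: float = 300.0):
    """Convert a potential from internal e/Å units to k_BT/e at ``temperature``."""
    return phi_e_per_A * E2_KCAL_MOL_A / (KB_KCAL_MOL_K * temperature)


def surface_density_to_e_A2(sigma_uC_cm2):
    """Convert a surface charge (or polarization) density from μC/cm² to e/Å²."""
    return sigma_uC_cm2 * UC_CM2_TO_E_A2
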