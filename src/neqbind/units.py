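"""Physical constants and unit conversions.

Internal units throughout the package: lengths in nm, energies in kJ/mol,
times in ps, temperatures in K. Path-metric quantities (the orthogonal
collective variable Z, wall thresholds) are mean square deviations and
carry nm².
"""

from __future__ import annotations

#: Boltzmann constant, kJ/mol/K (CODATA, as used by common MD engines).
KB_KJ_PER_MOL_K: float = 0.0083144621

#: Boltzmann constant, kcal/mol/K.
KB_KCAL_PER_MOL_K: float = 1.9872041e-3

#: kJ per kcal (thermochemical calorie).
KJ_PER_KCAL: float = 4.184

#: Avogadro's number, 1/mol.
N_AVOGADRO: float = 6.02214076e23

#: Standard-state volume per molecule at 1 M, Å³, as conventionally printed.
V_STANDARD_A3: float = 1661.0

ANGSTROM_PER_NM: float = 10.0


def standard_state_volume() -> float:
    """Volume per molecule at 1 mol/L, in Å³, computed from Avogadro's number.

    1 L = 1e27 Å³, so V° = 1e27 / N_A ≈ 1660.5 Å³, conventionally quoted
    as 1661 Å³.
    """
    return 1e27 / N_AVOGADRO


def beta_from_temperature(temperature: float) -> float:
    """Inverse thermal energy β = 1/(k_B T) in mol/kJ."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB_KJ_PER_MOL_K * temperature)


def kt(temperature: float) -> float:
    """Thermal energy k_B T in kJ/mol."""
    return KB_KJ_PER_MOL_K * temperature
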