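"""Unit conventions and physical constants.

The package works in a single unit system throughout:

==============  =========================
length          nm
time            ns
energy          kJ/mol
force           kJ/mol/nm
charge          elementary charges (e)
field           V/nm
voltage         V
current         pA
conductance     pS
temperature     K
==============  =========================

No function silently converts between unit systems; every conversion factor
used anywhere in the package lives here.
"""

from __future__ import annotations

#: Boltzmann constant in kJ/mol/K (molar gas constant / 1000).
BOLTZMANN_KJ_PER_MOL_K: float = 0.008314462618

#: Elementary charge in coulomb.
ELEMENTARY_CHARGE_C: float = 1.602176634e-19

#: Force, in kJ/mol/nm, on a +1 e charge in a 1 V/nm field (Faraday/1000).
FIELD_FORCE_KJ_PER_MOL_NM_PER_E_V_NM: float = 96.48533212

#: Volume per molecule at the 1 mol/L standard concentration, nm^3.
STANDARD_VOLUME_NM3: float = 1.6606

#: pA carried by one elementary charge per ns: e[C] / 1 ns * 1e12 pA/A.
PICOAMP_PER_E_PER_NS: float = ELEMENTARY_CHARGE_C / 1e-9 * 1e12


def thermal_energy(temperature: float) -> float:
    """kT in kJ/mol at the given temperature in K (2.494 kJ/mol at 300 K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return BOLTZMANN_KJ_PER_MOL_K * temperature
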