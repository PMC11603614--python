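"""Physical constants and unit conversions.

Internal units everywhere: kJ/mol, nm, ps, K.  kcal/mol appears only at
reporting boundaries (binding free energies, affinity tables).
"""

from __future__ import annotations

#: Boltzmann constant in kJ/(mol K)
KB = 0.008314462618

#: thermochemical calorie
KJ_PER_KCAL = 4.184

#: standard concentration 1 M expressed as 1/1660 A^-3, converted to nm^-3
C0_PER_NM3 = 1.0 / 1660.0 * 1000.0

#: default thermostat temperature (K)
DEFAULT_TEMPERATURE = 298.0


def kjmol_to_kcalmol(x: float) -> float:
    return x / KJ_PER_KCAL


def kcalmol_to_kjmol(x: float) -> float:
    return x * KJ_PER_KCAL


def kbt(temperature: float) -> float:
    """kB*T in kJ/mol."""
    return KB * temperature
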