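"""Unit constants and conversions.

Work values and free energies are handled in kJ/mol internally (GROMACS
convention); benchmark-level ΔΔG, UE and AUE are reported in kcal/mol
(the convention of the experimental binding literature).
"""

#: kJ/mol per kcal/mol (thermochemical calorie).
KJ_PER_KCAL = 4.184

#: Boltzmann constant in kJ/(mol·K).
KB_KJ_MOL = 0.008314462618

#: kT at 298.15 K in kJ/mol (~2.479). Default thermal energy throughout.
KT_298 = KB_KJ_MOL * 298.15


def kj_to_kcal(x):
    """Convert kJ/mol to kcal/mol."""
    return x / KJ_PER_KCAL


def kcal_to_kj(x):
    """Convert kcal/mol to kJ/mol."""
    return x * KJ_PER_KCAL
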