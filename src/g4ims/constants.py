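"""Physical constants and elemental masses used throughout the package.

Physical constants come from :mod:`scipy.constants` (CODATA); elemental
masses are IUPAC standard atomic weights (average) and CODATA monoisotopic
masses.  Residue masses are always derived from elemental composition
rather than hard-coded, so they can be audited against any composition
calculator.
"""

from __future__ import annotations

from scipy import constants as _const

# --- physics ---------------------------------------------------------------
ELEMENTARY_CHARGE = _const.e  # C
BOLTZMANN = _const.k  # J/K
EPSILON_0 = _const.epsilon_0  # F/m
DA_TO_KG = _const.u  # kg per dalton

#: Average proton mass in Da used for deprotonation arithmetic (negative mode).
PROTON_MASS_DA = 1.00728

#: Helium buffer-gas mass (Da, average).
HELIUM_MASS_DA = 4.0026

# --- chemistry -------------------------------------------------------------
#: IUPAC standard atomic weights (Da).
AVERAGE_WEIGHTS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.973761998,
}

#: Monoisotopic masses (Da).
MONOISOTOPIC_WEIGHTS = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
}

#: Elemental composition of the 2'-deoxyribonucleosides (free nucleoside,
#: i.e. base + deoxyribose).  Phosphodiester linkages are accounted for
#: separately (one HPO3 added and one H2O removed per linkage).
DEOXYNUCLEOSIDES = {
    "A": {"C": 10, "H": 13, "N": 5, "O": 3},
    "C": {"C": 9, "H": 13, "N": 3, "O": 4},
    "G": {"C": 10, "H": 13, "N": 5, "O": 4},
    "T": {"C": 10, "H": 14, "N": 2, "O": 5},
}

WATER = {"H": 2, "O": 1}
HPO3 = {"H": 1, "P": 1, "O": 3}
#: NH3, the net mass added when an NH4+ replaces an H+ on a phosphate.
AMMONIA = {"N": 1, "H": 3}


def formula_mass(formula: dict[str, int], monoisotopic: bool = False) -> float:
    """Mass (Da) of an elemental formula given as an element->count mapping."""
    weights = MONOISOTOPIC_WEIGHTS if monoisotopic else AVERAGE_WEIGHTS
    return sum(weights[el] * n for el, n in formula.items())


def nh4_adduct_mass(monoisotopic: bool = False) -> float:
    """Net mass shift (Da) for one ammonium adduct (NH4+ replacing H+)."""
    return formula_mass(AMMONIA, monoisotopic)
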