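"""Electrospray ionization scenario inference for multidomain nucleic acids.

Three limiting ESI scenarios are considered for negative-mode DNA:

* CRM (charged residue): the droplet evaporates to dryness; the ion's
  charge cannot exceed the Rayleigh limit of an analyte-sized droplet and
  the resulting structures are compact/globular.
* CEM (chain ejection): an unstructured chain extrudes from the droplet,
  carrying many charges; structures are extended and folded subunits
  (hence inner ammoniums) are lost.
* BEM (bead ejection): hybrid — folded domains stay compact ("beads",
  local CRM) while unstructured linkers eject (local CEM); the signature
  is charging above the Rayleigh limit *with* retained inner NH4+ ions.

Each observed population (charge z, modal ammonium count, compactness
class) is classified by a fixed, total rule table over
(above-Rayleigh?, NH4+ retention, compactness).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import DA_TO_KG, ELEMENTARY_CHARGE, EPSILON_0
from .sequences import OligoSequence

__all__ = [
    "RayleighResult",
    "ScenarioCall",
    "analyte_mass",
    "rayleigh_limit",
    "charge_density",
    "nh4_retention",
    "classify_scenario",
    "discriminative_window",
    "DEFAULT_SURFACE_TENSION",
    "DEFAULT_DENSITY",
]

#: Water density (kg/m^3) for the equivalent-mass droplet.
DEFAULT_DENSITY = 1000.0
#: Water surface tension (N/m) at room temperature.
DEFAULT_SURFACE_TENSION = 0.073


@dataclass(frozen=True)
class RayleighResult:
    """Rayleigh charge limit of a water droplet of the analyte's mass."""

    z_r: float
    droplet_radius_m: float
    mass_da: float
    density: float
    surface_tension: float
    zr_over_p: float | None = None


@dataclass(frozen=True)
class ScenarioCall:
    population: tuple[int, int, str]  # (z, modal n_nh4, compactness label)
    z_over_p: float
    above_rayleigh: bool
    nh4_retention: str  # full | partial | none
    call: str  # CRM | BEM | CEM | ambiguous
    rationale: str


def analyte_mass(seq: OligoSequence) -> float:
    """Mass (Da) of the analyte as sprayed: strand plus its inner ammoniums.

    A folded G4 construct enters the droplet with its specifically bound
    NH4+ ions; the equivalent-mass droplet of the Rayleigh analysis is
    built on that species (declared count if present, else the expected
    2 per subunit).
    """
    from .constants import nh4_adduct_mass

    n = seq.declared_nh4 if seq.declared_nh4 is not None else seq.n_inner_nh4_expected
    return seq.mass() + n * nh4_adduct_mass()


def rayleigh_limit(
    mass_da: float,
    density: float = DEFAULT_DENSITY,
    surface_tension: float = DEFAULT_SURFACE_TENSION,
    seq: OligoSequence | None = None,
) -> RayleighResult:
    """Rayleigh limit charge z_R of a water droplet with the analyte's mass.

    R = (3m / 4 pi rho)^(1/3); z_R e = 8 pi sqrt(eps0 * gamma * R^3).
    Since R^3 is proportional to m, z_R scales as sqrt(m).  When a sequence
    is attached, the charged-phosphate fraction z_R/P is reported too.
    """
    if mass_da <= 0 or density <= 0 or surface_tension <= 0:
        raise ValueError("mass, density and surface tension must be positive")
    m_kg = mass_da * DA_TO_KG
    r3 = 3.0 * m_kg / (4.0 * math.pi * density)
    z_r = 8.0 * math.pi * math.sqrt(EPSILON_0 * surface_tension * r3) / ELEMENTARY_CHARGE
    return RayleighResult(
        z_r=z_r,
        droplet_radius_m=r3 ** (1.0 / 3.0),
        mass_da=mass_da,
        density=density,
        surface_tension=surface_tension,
        zr_over_p=z_r / seq.n_phosphates if seq is not None else None,
    )


def charge_density(z: int, seq: OligoSequence) -> float:
    """Charge-to-phosphate ratio z/P, the charge-density proxy for DNA."""
    if z < 1:
        raise ValueError("z must be >= 1")
    return z / seq.n_phosphates


def discriminative_window(z: int, seq: OligoSequence) -> bool:
    """True iff 0.25 < z/P < 0.35 (strict), the charge-density window in
    which CCS best discriminates preserved folded domains: below it all
    ions are equally compact; above it the folds are disrupted anyway."""
    zp = charge_density(z, seq)
    return 0.25 < zp < 0.35


def nh4_retention(modal_n_nh4: int, expected: int) -> str:
    """Retention class of inner ammoniums vs the sequence's expectation.

    full: all expected inner NH4+ retained (only meaningful if any are
    expected); partial: some lost; none: all lost, or nothing to retain.
    """
    if modal_n_nh4 < 0 or expected < 0:
        raise ValueError("counts must be non-negative")
    if expected == 0 or modal_n_nh4 == 0:
        return "none"
    if modal_n_nh4 >= expected:
        return "full"
    return "partial"


_RULES: dict[tuple[bool, str, str], tuple[str, str]] = {}


def _rule(above: bool, retention: str, compactness: str) -> tuple[str, str]:
    """Total rule table over (above-Rayleigh, retention, compactness)."""
    if not above:
        if compactness == "compact":
            return "CRM", (
                "charge at or below the Rayleigh limit with a globular "
                "structure: charged-residue scenario"
            )
        return "ambiguous", (
            "sub-Rayleigh charge but non-globular structure: pattern not "
            "covered by the scenario rules"
        )
    if retention == "partial":
        return "BEM", (
            "supra-Rayleigh charge with partial inner-NH4+ retention: "
            "bead ejection with partial bead loss"
        )
    if retention == "full":
        return "BEM", (
            "supra-Rayleigh charge with all inner NH4+ retained: folded "
            "beads plus ejected linkers (bead ejection)"
        )
    # retention == "none"
    if compactness == "extended":
        return "CEM", (
            "supra-Rayleigh charge, no inner NH4+, fully extended: chain "
            "ejection suffices"
        )
    if compactness == "compact":
        return "ambiguous", (
            "supra-Rayleigh compact ion without inner NH4+: pattern not "
            "covered by the scenario rules"
        )
    # intermediate or gap
    return "ambiguous", (
        "supra-Rayleigh, no inner NH4+, intermediate extension: either "
        "direct chain ejection or bead ejection followed by Coulomb "
        "unfolding; the data cannot distinguish them"
    )


for _above in (False, True):
    for _ret in ("full", "partial", "none"):
        for _cpt in ("compact", "gap", "intermediate", "extended"):
            _RULES[(_above, _ret, _cpt)] = _rule(_above, _ret, _cpt)


def classify_scenario(
    population: tuple[int, int, str],
    seq: OligoSequence,
    rayleigh: RayleighResult,
) -> ScenarioCall:
    """Classify one (z, modal n_NH4, compactness) population as CRM/BEM/CEM.

    "Significantly below the Rayleigh limit" is operationalised as
    z <= floor(z_R).  The call uses only (z vs z_R, NH4+ retention vs the
    sequence's expected inner-ammonium count, compactness class); ionic
    strength is reported as metadata, never used in the rule.
    """
    z, modal_n, compactness = population
    if compactness not in ("compact", "gap", "intermediate", "extended"):
        raise ValueError(f"unknown compactness label {compactness!r}")
    above = z > math.floor(rayleigh.z_r)
    retention = nh4_retention(modal_n, seq.n_inner_nh4_expected)
    call, rationale = _RULES[(above, retention, compactness)]
    return ScenarioCall(
        population=(z, modal_n, compactness),
        z_over_p=charge_density(z, seq),
        above_rayleigh=above,
        nh4_retention=retention,
        call=call,
        rationale=rationale,
    )
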