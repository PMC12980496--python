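"""Ion species enumeration: (charge, ammonium count) -> m/z.

Negative-mode electrospray of DNA produces [M - zH + n(NH4)]^z- ions; the
net mass shift per ammonium adduct is +NH3 (the NH4+ replaces a proton on a
phosphate).  Noncovalent multimolecular assemblies (e.g. the tetramolecular
[ (dTG4T)4 (NH4)3 ]5- quality-control G-quadruplex) have a neutral mass
equal to the sum of their strand masses.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import PROTON_MASS_DA, nh4_adduct_mass
from .sequences import OligoSequence, average_mass, parse_shorthand

__all__ = ["IonSpecies", "enumerate_species", "tg4t_reference_ion"]


@dataclass(frozen=True)
class IonSpecies:
    """One (z, n_NH4) ion of a strand or noncovalent strand assembly.

    ``z`` is the magnitude of the negative charge; ``assembly`` the number
    of strands in the (noncovalent) complex.
    """

    sequence: OligoSequence
    z: int
    n_nh4: int = 0
    assembly: int = 1
    monoisotopic: bool = False

    def __post_init__(self) -> None:
        if self.z < 1:
            raise ValueError("charge magnitude z must be >= 1")
        if self.n_nh4 < 0:
            raise ValueError("ammonium count must be >= 0")

    @property
    def neutral_mass(self) -> float:
        """Mass (Da) of the neutral, adduct-free assembly."""
        return self.assembly * average_mass(self.sequence, self.monoisotopic)

    @property
    def ion_mass(self) -> float:
        """Mass (Da) of the drifting ion: neutral + adducts - z protons."""
        return (
            self.neutral_mass
            + self.n_nh4 * nh4_adduct_mass(self.monoisotopic)
            - self.z * PROTON_MASS_DA
        )

    @property
    def mz(self) -> float:
        return self.ion_mass / self.z

    @property
    def label(self) -> str:
        core = self.sequence.name
        if self.assembly > 1:
            core = f"({core}){self.assembly}"
        if self.n_nh4:
            core += f"(NH4){self.n_nh4}"
        return f"[{core}]{self.z}-"


def enumerate_species(
    seq: OligoSequence,
    z_range,
    n_nh4_range,
    assembly: int = 1,
) -> list[IonSpecies]:
    """All (z, n) candidate ions of ``seq``, sorted by m/z.

    Raises if either range is empty or contains a non-positive charge.
    """
    z_list = list(z_range)
    n_list = list(n_nh4_range)
    if not z_list or not n_list:
        raise ValueError("z_range and n_nh4_range must be non-empty")
    if any(z < 1 for z in z_list):
        raise ValueError("z_range must contain positive charge magnitudes only")
    species = [
        IonSpecies(seq, z=z, n_nh4=n, assembly=assembly)
        for z in z_list
        for n in n_list
    ]
    return sorted(species, key=lambda s: s.mz)


def tg4t_reference_ion() -> IonSpecies:
    """The tetramolecular [(dTG4T)4(NH4)3]5- CCS quality-control ion."""
    strand = parse_shorthand("dTG4T", name="dTG4T")
    return IonSpecies(strand, z=5, n_nh4=3, assembly=4)
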