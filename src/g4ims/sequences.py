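"""DNA sequence shorthand parsing, masses, and G-quadruplex subunit counting.

Sequences are written in a compact shorthand commonly used for designed
oligonucleotides, e.g. ``dT(TG3)4T43·(NH4+)2``: an optional leading ``d``
(DNA), base letters with optional repeat counts, parenthesised groups with
repeat counts, and an optional ``·(NH4+)k`` suffix declaring the number of
specifically bound inner ammonium ions.  Square brackets and whitespace are
ignored.

A G-quadruplex (G4) subunit is detected on the expanded base string as four
G-tracts of at least three guanines separated by loops of one or two
non-G bases; each such three-quartet subunit specifically coordinates two
inner NH4+ ions between its quartets.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

from .constants import (
    DEOXYNUCLEOSIDES,
    HPO3,
    WATER,
    formula_mass,
)

__all__ = [
    "OligoSequence",
    "ShorthandParseError",
    "UnsupportedAlphabetError",
    "parse_shorthand",
    "count_g4_subunits",
    "average_mass",
    "elemental_composition",
    "read_fasta",
]

#: Four G-tracts (>=3 G) separated by loops of 1-2 non-G bases.
G4_MOTIF = re.compile(r"G{3,}(?:[ACT]{1,2}G{3,}){3}")

#: ``·(NH4+)k`` suffix, also accepting "." as the separator dot and an
#: optional closing bracket after it.
_NH4_SUFFIX = re.compile(r"[·.]\s*\(NH4\s*\+?\)\s*(\d+)\s*\]?\s*$")

_IGNORED = set(" \t[]")


class ShorthandParseError(ValueError):
    """Malformed shorthand; carries the 0-based offset of the offence."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class UnsupportedAlphabetError(ShorthandParseError):
    """A letter outside the DNA alphabet A/C/G/T."""


@dataclass(frozen=True)
class OligoSequence:
    """A parsed linear DNA strand (5'-OH, 3'-OH, no terminal phosphate)."""

    name: str
    expanded_bases: str
    declared_nh4: int | None = None
    shorthand: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.expanded_bases:
            raise ValueError("empty sequence")
        bad = set(self.expanded_bases) - set("ACGT")
        if bad:
            raise UnsupportedAlphabetError(
                f"non-DNA letters {sorted(bad)}", self.expanded_bases.index(bad.pop())
            )

    @property
    def n_bases(self) -> int:
        return len(self.expanded_bases)

    @property
    def n_phosphates(self) -> int:
        """Phosphodiester linkages of a linear strand: one fewer than bases."""
        return self.n_bases - 1

    @property
    def base_counts(self) -> Counter:
        return Counter(self.expanded_bases)

    @property
    def n_g4_subunits(self) -> int:
        return count_g4_subunits(self)

    @property
    def n_inner_nh4_expected(self) -> int:
        """Two specifically bound NH4+ per three-quartet G4 subunit."""
        return 2 * self.n_g4_subunits

    def to_shorthand(self) -> str:
        """Run-length-encode the expanded bases (e.g. TTT -> T3)."""
        out = []
        for match in re.finditer(r"(.)\1*", self.expanded_bases):
            run = match.group(0)
            out.append(run[0] + (str(len(run)) if len(run) > 1 else ""))
        return "d" + "".join(out)

    def mass(self, monoisotopic: bool = False) -> float:
        return average_mass(self, monoisotopic=monoisotopic)


def parse_shorthand(text: str, name: str | None = None) -> OligoSequence:
    """Parse sequence shorthand into an :class:`OligoSequence`.

    Grammar: optional ``d`` prefix; tokens are a base letter optionally
    followed by a repeat count, or a parenthesised group followed by a
    repeat count; an optional ``·(NH4+)k`` suffix declares inner ammoniums.
    Repeat digits bind to the immediately preceding base or group.
    """
    declared_nh4 = None
    m = _NH4_SUFFIX.search(text)
    body_end = len(text)
    if m:
        declared_nh4 = int(m.group(1))
        body_end = m.start()

    i = 0
    # skip ignorable chars before the optional "d" prefix
    while i < body_end and text[i] in _IGNORED:
        i += 1
    if i < body_end and text[i] == "d":
        i += 1

    def parse_group(i: int, depth: int) -> tuple[str, int]:
        parts: list[str] = []
        while i < body_end:
            ch = text[i]
            if ch in _IGNORED:
                i += 1
            elif ch == "(":
                inner, i = parse_group(i + 1, depth + 1)
                if i >= body_end or text[i] != ")":
                    raise ShorthandParseError("unclosed group", i)
                i += 1
                count, i = _read_digits(text, i, body_end)
                parts.append(inner * count)
            elif ch == ")":
                if depth == 0:
                    raise ShorthandParseError("unmatched ')'", i)
                return "".join(parts), i
            elif ch.isalpha():
                if ch not in "ACGT":
                    raise UnsupportedAlphabetError(f"unsupported letter {ch!r}", i)
                i += 1
                count, i = _read_digits(text, i, body_end)
                parts.append(ch * count)
            else:
                raise ShorthandParseError(f"unexpected character {ch!r}", i)
        if depth != 0:
            raise ShorthandParseError("unclosed group", i)
        return "".join(parts), i

    expanded, _ = parse_group(i, 0)
    if not expanded:
        raise ShorthandParseError("empty sequence", 0)
    return OligoSequence(
        name=name or text.strip(),
        expanded_bases=expanded,
        declared_nh4=declared_nh4,
        shorthand=text,
    )


def _read_digits(text: str, i: int, end: int) -> tuple[int, int]:
    j = i
    while j < end and text[j].isdigit():
        j += 1
    if j == i:
        return 1, i
    return int(text[i:j]), j


def count_g4_subunits(seq: OligoSequence) -> int:
    """Non-overlapping, left-to-right count of four-G-tract G4 motifs."""
    return sum(1 for _ in G4_MOTIF.finditer(seq.expanded_bases))


def elemental_composition(seq: OligoSequence) -> Counter:
    """Elemental formula of the neutral strand (5'-OH/3'-OH, n-1 phosphates)."""
    comp: Counter = Counter()
    for base, n in seq.base_counts.items():
        for el, k in DEOXYNUCLEOSIDES[base].items():
            comp[el] += k * n
    # each phosphodiester linkage adds HPO3 and removes H2O
    for el, k in HPO3.items():
        comp[el] += k * seq.n_phosphates
    for el, k in WATER.items():
        comp[el] -= k * seq.n_phosphates
    return comp


def average_mass(seq: OligoSequence, monoisotopic: bool = False) -> float:
    """Neutral strand mass (Da) from elemental composition.

    Average masses are the default: at the charge states relevant here
    (z = 5-26 on ~18.5 kDa strands) isotopes are unresolved.
    """
    return formula_mass(elemental_composition(seq), monoisotopic=monoisotopic)


def read_fasta(path) -> list[OligoSequence]:
    """Read expanded-base DNA sequences from a FASTA file."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(OligoSequence(name=rec.id, expanded_bases=str(rec.seq).upper()))
    return records
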