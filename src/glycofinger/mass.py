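"""Monoisotopic mass calculus for reducing, sodiated N-glycan compositions.

A glycan is described at composition level only: counts of hexoses (Hex),
N-acetylhexosamines (HexNAc), pentoses (Pen), O-methyl groups (Me) and,
when it is known, deoxyhexoses (dHex).  A deoxyhexose has the same
elemental formula (C6H10O4) as a methylated pentose, so on MS1 evidence
alone a dHex is indistinguishable from one Pen plus one Me; compositions
therefore have a canonical *folded* form in which every dHex is counted as
Pen + Me.  The "os" shorthand used throughout this package (e.g. os3231 =
Hex3 HexNAc2 Pen3 Me1) always refers to the folded form.

All masses are monoisotopic and in daltons.  The MALDI default ion species
is the singly sodiated, underivatized reducing glycan, [M+Na]+.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace

__all__ = [
    "MassConstants",
    "MONOISOTOPIC",
    "CONSTANTS_VERSION",
    "GlycanComposition",
    "IonSpecies",
    "SODIATED",
    "neutral_mass",
    "ion_mz",
    "format_os_code",
    "parse_os_code",
    "add_core_fucose",
    "export_constants",
    "CompositionError",
    "OsCodeError",
    "SubstrateError",
]

CONSTANTS_VERSION = "1.0.0"

#: mass of two hydrogen atoms, gained on reduction of the free reducing end
_H2 = 2.01565


class CompositionError(ValueError):
    """Raised for invalid residue counts or ion species."""


class OsCodeError(ValueError):
    """Raised when an os composition code cannot be parsed."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class SubstrateError(ValueError):
    """Raised when an in-silico enzyme is offered a non-substrate."""


@dataclass(frozen=True)
class MassConstants:
    """Monoisotopic residue and adduct masses, in Da.

    Residue masses are dehydrated (glycosidically linked) monomers; a free
    oligosaccharide is the sum of residues plus one water.  The sodium
    cation mass is electron-corrected.  A deoxyhexose must equal pentose
    plus methyl exactly, since both share the C6H10O4 formula.
    """

    hex: float = 162.05282
    hexnac: float = 203.07937
    pen: float = 132.04226
    me: float = 14.01565
    dhex: float = 146.05791
    water: float = 18.01056
    sodium_cation: float = 22.98922
    proton: float = 1.00728

    def __post_init__(self):
        for name in ("hex", "hexnac", "pen", "me", "dhex", "water",
                     "sodium_cation", "proton"):
            if getattr(self, name) <= 0:
                raise CompositionError(f"mass constant {name!r} must be positive")
        if abs(self.dhex - (self.pen + self.me)) > 1e-9:
            raise CompositionError(
                "dhex must equal pen + me exactly (identical elemental formula)"
            )

    def as_dict(self) -> dict:
        return {
            "version": CONSTANTS_VERSION,
            "units": "Da, monoisotopic",
            "hex": self.hex,
            "hexnac": self.hexnac,
            "pen": self.pen,
            "me": self.me,
            "dhex": self.dhex,
            "water": self.water,
            "sodium_cation": self.sodium_cation,
            "proton": self.proton,
        }


MONOISOTOPIC = MassConstants()


def export_constants(path=None, constants: MassConstants = MONOISOTOPIC) -> dict:
    """Return the mass constants as a versioned dict; optionally write JSON.

    Downstream reports can embed this dict so every reported m/z is
    traceable to the constant set that produced it.
    """
    payload = constants.as_dict()
    if path is not None:
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    return payload


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Counts of Hex, HexNAc, Pen, Me and (optionally) dHex residues.

    ``n_dhex`` is kept separate only when the deoxyhexose is actually known
    (e.g. from an enzymatic transfer); MS1 assignment always reports the
    folded form.  Two compositions that fold to the same counts have
    identical mass.
    """

    n_hex: int = 0
    n_hexnac: int = 0
    n_pen: int = 0
    n_me: int = 0
    n_dhex: int = 0

    def __post_init__(self):
        for name in ("n_hex", "n_hexnac", "n_pen", "n_me", "n_dhex"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise CompositionError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total_residues(self) -> int:
        return self.n_hex + self.n_hexnac + self.n_pen + self.n_me + self.n_dhex

    @property
    def is_n_glycan(self) -> bool:
        """True when the chitobiose core (two HexNAc) can be present."""
        return self.n_hexnac >= 2

    @property
    def is_oligomannosidic(self) -> bool:
        """Hex_n HexNAc_2 with no pentose/methyl/deoxyhexose decoration."""
        return (self.n_hexnac == 2 and self.n_pen == 0 and self.n_me == 0
                and self.n_dhex == 0 and self.n_hex >= 1)

    def fold_dhex(self) -> "GlycanComposition":
        """Canonical form: count every dHex as one Pen plus one Me."""
        if self.n_dhex == 0:
            return self
        return GlycanComposition(
            n_hex=self.n_hex,
            n_hexnac=self.n_hexnac,
            n_pen=self.n_pen + self.n_dhex,
            n_me=self.n_me + self.n_dhex,
            n_dhex=0,
        )

    def combine(self, other: "GlycanComposition") -> "GlycanComposition":
        """Residue-wise sum (the glycosidic union of two compositions)."""
        return GlycanComposition(
            self.n_hex + other.n_hex,
            self.n_hexnac + other.n_hexnac,
            self.n_pen + other.n_pen,
            self.n_me + other.n_me,
            self.n_dhex + other.n_dhex,
        )

    def minus(self, other: "GlycanComposition") -> "GlycanComposition":
        """Residue-wise difference; raises if any count would go negative."""
        return GlycanComposition(
            self.n_hex - other.n_hex,
            self.n_hexnac - other.n_hexnac,
            self.n_pen - other.n_pen,
            self.n_me - other.n_me,
            self.n_dhex - other.n_dhex,
        )

    def contains(self, other: "GlycanComposition") -> bool:
        return (self.n_hex >= other.n_hex and self.n_hexnac >= other.n_hexnac
                and self.n_pen >= other.n_pen and self.n_me >= other.n_me
                and self.n_dhex >= other.n_dhex)

    @property
    def os_code(self) -> str:
        return format_os_code(self)

    def __str__(self) -> str:
        parts = []
        for label, n in (("Hex", self.n_hex), ("HexNAc", self.n_hexnac),
                         ("Pen", self.n_pen), ("Me", self.n_me),
                         ("dHex", self.n_dhex)):
            if n:
                parts.append(f"{label}{n}")
        return "".join(parts) or "empty"


@dataclass(frozen=True)
class IonSpecies:
    """Adduct, charge and reducing-end state of a measured glycan ion."""

    adduct: str = "sodiated"
    charge: int = 1
    reduced: bool = False

    def __post_init__(self):
        if self.adduct not in ("sodiated", "protonated"):
            raise CompositionError(f"unsupported adduct {self.adduct!r}")
        if not isinstance(self.charge, int) or self.charge < 1:
            raise CompositionError("charge must be a positive integer")


#: MALDI default: singly sodiated, underivatized reducing glycan
SODIATED = IonSpecies()


def residue_mass(c: GlycanComposition, constants: MassConstants = MONOISOTOPIC) -> float:
    """Sum of dehydrated residue masses (no terminal water)."""
    return (c.n_hex * constants.hex + c.n_hexnac * constants.hexnac
            + c.n_pen * constants.pen + c.n_me * constants.me
            + c.n_dhex * constants.dhex)


def neutral_mass(c: GlycanComposition, constants: MassConstants = MONOISOTOPIC) -> float:
    """Neutral monoisotopic mass of the free (reducing) oligosaccharide."""
    return residue_mass(c, constants) + constants.water


def ion_mz(c: GlycanComposition, ion: IonSpecies = SODIATED,
           constants: MassConstants = MONOISOTOPIC) -> float:
    """m/z of the composition under the given ion species.

    Reduction (alditol) adds two hydrogen atoms to the neutral mass before
    the adduct.  For charge z the m/z is (M + z * carrier) / z.
    """
    m = neutral_mass(c, constants)
    if ion.reduced:
        m += _H2
    carrier = constants.sodium_cation if ion.adduct == "sodiated" else constants.proton
    return (m + ion.charge * carrier) / ion.charge


_OS_FIELD = re.compile(r"\[(\d+)\]|(\d)")


def format_os_code(c: GlycanComposition) -> str:
    """Composition shorthand: 'os' + Hex, HexNAc, Pen, Me counts.

    Any dHex is folded into Pen + Me first.  Counts of ten or more are
    bracketed, e.g. Hex10 HexNAc2 Pen1 Me3 -> "os[10]213".
    """
    f = c.fold_dhex()
    fields = []
    for n in (f.n_hex, f.n_hexnac, f.n_pen, f.n_me):
        fields.append(str(n) if n < 10 else f"[{n}]")
    return "os" + "".join(fields)


def parse_os_code(code: str) -> GlycanComposition:
    """Inverse of :func:`format_os_code`; raises :class:`OsCodeError`."""
    if not isinstance(code, str) or not code.startswith("os"):
        raise OsCodeError(f"os code must start with 'os': {code!r}", 0)
    pos = 2
    counts = []
    for _ in range(4):
        m = _OS_FIELD.match(code, pos)
        if m is None:
            raise OsCodeError(f"expected a digit or bracketed count in {code!r}", pos)
        counts.append(int(m.group(1) if m.group(1) is not None else m.group(2)))
        pos = m.end()
    if pos != len(code):
        raise OsCodeError(f"trailing characters in {code!r}", pos)
    return GlycanComposition(n_hex=counts[0], n_hexnac=counts[1],
                             n_pen=counts[2], n_me=counts[3])


def add_core_fucose(c: GlycanComposition,
                    constants: MassConstants = MONOISOTOPIC) -> GlycanComposition:
    """In-silico core alpha1,6-fucosyltransferase: add one dHex.

    The enzyme requires the GlcNAc-transferase-I product (an antennary
    GlcNAc beyond the chitobiose core, i.e. HexNAc >= 3, the Man5Gn
    situation) and a core not already fucosylated; a single transfer is
    modeled.  Plain oligomannosidic input such as Man5 (Hex5HexNAc2) is
    rejected, mirroring the substrate specificity of the enzyme.
    """
    if c.n_hexnac < 3:
        raise SubstrateError(
            f"{c.os_code}: no antennary GlcNAc (HexNAc >= 3 required); "
            "not a core alpha1,6-fucosyltransferase substrate"
        )
    if c.n_dhex >= 1:
        raise SubstrateError(f"{c.os_code}: core already fucosylated; single transfer modeled")
    return replace(c, n_dhex=c.n_dhex + 1)
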