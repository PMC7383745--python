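"""MS2 (LIFT) fragment enumeration and core-substitution inference.

For a sodiated reducing N-glycan precursor every composition bipartition
yields a complementary y/b ion pair:

    m(y) = retained residues + water + Na
    m(b) = retained residues + Na
    m(b) + m(y) = precursor [M+Na]+ m/z + m(Na)

On top of the bipartitions, four diagnostic neutral losses are tracked,
because the interpretation rules hinge on them:

    -221.09  loss of the free reducing-end GlcNAc (GlcNAc + water)
    -203.08  loss of a second, unsubstituted GlcNAc
    -217.09  loss of a methylated GlcNAc
    -146.06  loss of a deoxyhexose (core fucose candidate)

Inference is composition-level only: which residue carries a methyl group
or a linkage position is NMR territory and out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .mass import (
    MONOISOTOPIC,
    GlycanComposition,
    MassConstants,
    SODIATED,
    ion_mz,
    residue_mass,
)
from .spectrum import Peak, Spectrum

__all__ = [
    "MS2_TOLERANCE",
    "FragmentIon",
    "FragmentMatch",
    "LiftMatchResult",
    "CoreEvidence",
    "enumerate_fragments",
    "match_lift",
    "infer_core",
    "pngase_release",
    "RELEASED_BY_F_AND_A",
    "RELEASED_BY_A_ONLY",
]

#: default LIFT match window, Da (printed LIFT values deviate up to ~0.3)
MS2_TOLERANCE = 0.3

LOSS_GN1 = "-1 Gn"
LOSS_GN2 = "-2 Gn"
LOSS_GN1_ME = "-1 Gn(Me)"
LOSS_GN2_ME = "-2 Gn(Me)"
LOSS_DHEX = "-dHex"
LOSS_DHEX_GN1 = "-dHex -1 Gn"

RELEASED_BY_F_AND_A = "released_by_F_and_A"
RELEASED_BY_A_ONLY = "released_by_A_only"


@dataclass(frozen=True)
class FragmentIon:
    """A b/y/internal/neutral-loss hypothesis for one precursor.

    ``retained`` is the composition kept in the ion (for a neutral loss:
    the precursor minus the lost residues).  ``label`` is the short name
    used in spectra annotation, e.g. "y:os2100" or "-1 Gn".
    """

    kind: str  # {"y", "b", "by-internal", "neutral-loss"}
    retained: GlycanComposition
    mz: float
    label: str


@dataclass(frozen=True)
class FragmentMatch:
    peak: Peak
    ion: FragmentIon
    error_da: float


@dataclass(frozen=True)
class LiftMatchResult:
    precursor: GlycanComposition
    matches: tuple[FragmentMatch, ...]
    unmatched_peaks: tuple[Peak, ...]

    def labels(self) -> set[str]:
        return {m.ion.label for m in self.matches}


def _subcompositions(c: GlycanComposition):
    """All residue-wise sub-compositions of a (folded) composition."""
    f = c.fold_dhex()
    for h in range(f.n_hex + 1):
        for n in range(f.n_hexnac + 1):
            for p in range(f.n_pen + 1):
                for m in range(f.n_me + 1):
                    yield GlycanComposition(h, n, p, m)


def enumerate_fragments(precursor: GlycanComposition,
                        constants: MassConstants = MONOISOTOPIC,
                        include_internal: bool = True) -> list[FragmentIon]:
    """Theoretical singly sodiated fragments of a reducing N-glycan.

    Emits a y ion for every non-empty sub-composition (the full
    composition included, equal to the precursor), a b ion for every
    proper non-empty sub-composition, internal (by) ions sharing the b-ion
    arithmetic, and the diagnostic neutral losses listed in the module
    docstring.  Order is deterministic: losses first, then y, b, internal,
    each sorted by composition counts.
    """
    prec = precursor.fold_dhex()
    if prec.n_hexnac < 2:
        raise ValueError(
            f"{precursor.os_code}: HexNAc < 2, not an N-glycan (chitobiose core required)"
        )
    na, water = constants.sodium_cation, constants.water
    prec_mz = ion_mz(prec, SODIATED, constants)
    gn_plus_water = constants.hexnac + water        # 221.09: free reducing GlcNAc
    gn = constants.hexnac                            # 203.08
    gn_me = constants.hexnac + constants.me          # 217.09: methylated GlcNAc
    dhex = constants.dhex                            # 146.06

    losses: list[FragmentIon] = []

    def loss(label, delta, lost):
        losses.append(FragmentIon(kind="neutral-loss", retained=prec.minus(lost),
                                  mz=prec_mz - delta, label=label))

    loss(LOSS_GN1, gn_plus_water, GlycanComposition(n_hexnac=1))
    loss(LOSS_GN2, gn_plus_water + gn, GlycanComposition(n_hexnac=2))
    if prec.n_me >= 1:
        loss(LOSS_GN1_ME, gn_me, GlycanComposition(n_hexnac=1, n_me=1))
        if prec.n_hexnac >= 2:
            loss(LOSS_GN2_ME, gn_plus_water + gn_me,
                 GlycanComposition(n_hexnac=2, n_me=1))
    has_dhex = precursor.n_dhex >= 1 or (prec.n_pen >= 1 and prec.n_me >= 1)
    if has_dhex:
        lost_dhex = GlycanComposition(n_pen=1, n_me=1)
        loss(LOSS_DHEX, dhex, lost_dhex)
        loss(LOSS_DHEX_GN1, dhex + gn_plus_water,
             lost_dhex.combine(GlycanComposition(n_hexnac=1)))

    y_ions, b_ions, internal = [], [], []
    for sub in _subcompositions(prec):
        if sub.total_residues == 0:
            continue
        y_ions.append(FragmentIon(
            kind="y", retained=sub,
            mz=residue_mass(sub, constants) + water + na,
            label=f"y:{sub.os_code}"))
        if sub != prec:
            b_ions.append(FragmentIon(
                kind="b", retained=sub,
                mz=residue_mass(sub, constants) + na,
                label=f"b:{sub.os_code}"))
            if include_internal:
                internal.append(FragmentIon(
                    kind="by-internal", retained=sub,
                    mz=residue_mass(sub, constants) + na,
                    label=f"by:{sub.os_code}"))
    return losses + y_ions + b_ions + internal


def match_lift(s: Spectrum, precursor: GlycanComposition,
               tol: float = MS2_TOLERANCE, precursor_tol: float = 0.5,
               constants: MassConstants = MONOISOTOPIC) -> LiftMatchResult:
    """Match an MS2 peak list against the theoretical fragments of a precursor.

    Every hypothesis within ``tol`` of a peak is reported (loss ions and b
    ions of the complementary composition are numerically identical, and
    both may legitimately explain one peak).  Peaks explained by no
    hypothesis are returned separately.
    """
    if s.level != "MS2":
        raise ValueError("match_lift expects an MS2 spectrum")
    prec_mz = ion_mz(precursor, SODIATED, constants)
    if abs(prec_mz - s.precursor_mz) > precursor_tol:
        raise ValueError(
            f"precursor composition {precursor.os_code} (m/z {prec_mz:.2f}) "
            f"inconsistent with declared precursor m/z {s.precursor_mz:.2f}"
        )
    ions = enumerate_fragments(precursor, constants)
    matches, unmatched = [], []
    for peak in s.peaks:
        hits = [FragmentMatch(peak, ion, peak.mz - ion.mz)
                for ion in ions if abs(peak.mz - ion.mz) <= tol]
        if hits:
            hits.sort(key=lambda m: (abs(m.error_da), m.ion.kind, m.ion.label))
            matches.extend(hits)
        else:
            unmatched.append(peak)
    return LiftMatchResult(precursor=precursor.fold_dhex(),
                           matches=tuple(matches),
                           unmatched_peaks=tuple(unmatched))


@dataclass(frozen=True)
class CoreEvidence:
    """Chitobiose-core substitution status inferred from LIFT evidence.

    Ternary fields take 'yes' / 'no' / 'unknown'; inference only ever
    upgrades unknown, never silently overwrites.  An unsubstituted
    chitobiose implies an unsubstituted GlcNAc-1.
    """

    glcnac1_unsubstituted: str = "unknown"
    chitobiose_unsubstituted: str = "unknown"
    glcnac2_substituted: str = "unknown"
    core13fucose: str = "unknown"
    methylated_hexnac_loss: bool = False
    supporting_ions: tuple[FragmentIon, ...] = field(default=(), compare=False)

    def __post_init__(self):
        for name in ("glcnac1_unsubstituted", "chitobiose_unsubstituted",
                     "glcnac2_substituted", "core13fucose"):
            if getattr(self, name) not in ("yes", "no", "unknown"):
                raise ValueError(f"{name} must be yes/no/unknown")
        if (self.chitobiose_unsubstituted == "yes"
                and self.glcnac1_unsubstituted == "no"):
            raise ValueError(
                "inconsistent evidence: unsubstituted chitobiose implies "
                "unsubstituted GlcNAc-1"
            )

    def as_dict(self) -> dict:
        return {
            "glcnac1_unsubstituted": self.glcnac1_unsubstituted,
            "chitobiose_unsubstituted": self.chitobiose_unsubstituted,
            "glcnac2_substituted": self.glcnac2_substituted,
            "core13fucose": self.core13fucose,
            "methylated_hexnac_loss": self.methylated_hexnac_loss,
        }


def infer_core(result: LiftMatchResult,
               precursor: GlycanComposition | None = None) -> CoreEvidence:
    """Apply the LIFT interpretation rules to a match result.

    R1  A direct -221.09 loss shows a free reducing-end GlcNAc: GlcNAc-1
        is unsubstituted and core alpha1,3-fucose is absent.
    R2  Consecutive losses -221.09 then -203.08 (or the -217.09 methylated
        variant) strip the whole chitobiose: the core is unsubstituted and
        GlcNAc-2 carries nothing.
    R3  If no reducing-side fragment (y or neutral loss) lacking both core
        GlcNAc residues is observed, while a complementary y/b pair splits
        the molecule right at the chitobiose (the y ion retaining exactly
        two HexNAc plus at least one further residue), GlcNAc-2 must carry
        a substituent.
    R4  If the -221.09 loss never occurs directly but only after a
        -146.06 deoxyhexose loss, the reducing GlcNAc carries a core
        1,3-linked fucose.

    Absent evidence degrades to 'unknown'; nothing is ever guessed.  A
    matched -217.09 (methylated GlcNAc) loss sets the
    ``methylated_hexnac_loss`` flag regardless of the rules above.
    """
    if precursor is None:
        precursor = result.precursor
    prec = precursor.fold_dhex()
    labels = result.labels()
    supporting: list[FragmentIon] = []

    def support(label):
        supporting.extend(m.ion for m in result.matches if m.ion.label == label)

    glcnac1 = chitobiose = glcnac2 = fucose = "unknown"
    me_loss = LOSS_GN1_ME in labels or LOSS_GN2_ME in labels
    if me_loss:
        support(LOSS_GN1_ME)

    # R1: free reducing-end GlcNAc
    if LOSS_GN1 in labels:
        glcnac1 = "yes"
        fucose = "no"
        support(LOSS_GN1)

    # R2: whole chitobiose stripped
    if LOSS_GN1 in labels and (LOSS_GN2 in labels or LOSS_GN2_ME in labels):
        chitobiose = "yes"
        glcnac2 = "no"
        support(LOSS_GN2)
        support(LOSS_GN2_ME)

    # R3: substitution of GlcNAc-2.  "A fragment lacking both core GlcNAc
    # residues" means the chitobiose was stripped entirely: a reducing-side
    # (y or loss) ion retaining no HexNAc at all, or an explicit second
    # GlcNAc loss.  The complement of a -1 Gn loss still holds GlcNAc-2
    # and does not count.
    if chitobiose == "unknown":
        reducing_side = [m for m in result.matches
                         if m.ion.kind in ("y", "neutral-loss")]
        lacks_core = (any(m.ion.retained.n_hexnac == 0 for m in reducing_side)
                      or LOSS_GN2 in labels or LOSS_GN2_ME in labels)
        split_pairs = []
        if not lacks_core:
            y_hits = {m.ion.retained: m.ion for m in result.matches
                      if m.ion.kind == "y"
                      and m.ion.retained.n_hexnac == 2
                      and m.ion.retained.total_residues > 2}
            b_hits = {m.ion.retained: m.ion for m in result.matches
                      if m.ion.kind == "b"}
            for y_ret, y_ion in y_hits.items():
                complement = prec.minus(y_ret)
                if complement in b_hits:
                    split_pairs.append((y_ion, b_hits[complement]))
        if split_pairs and not lacks_core:
            glcnac2 = "yes"
            chitobiose = "no"
            for y_ion, b_ion in split_pairs:
                supporting.extend((y_ion, b_ion))

    # R4: reducing GlcNAc released only after a deoxyhexose loss
    if LOSS_GN1 not in labels and LOSS_DHEX in labels and LOSS_DHEX_GN1 in labels:
        fucose = "yes"
        glcnac1 = "no"
        if chitobiose == "unknown":
            chitobiose = "no"
        support(LOSS_DHEX)
        support(LOSS_DHEX_GN1)

    return CoreEvidence(
        glcnac1_unsubstituted=glcnac1,
        chitobiose_unsubstituted=chitobiose,
        glcnac2_substituted=glcnac2,
        core13fucose=fucose,
        methylated_hexnac_loss=me_loss,
        supporting_ions=tuple(supporting),
    )


def pngase_release(core: CoreEvidence) -> str:
    """Predicted enzymatic release class of the glycan.

    PNGase F cannot cleave N-glycans carrying core 1,3-linked fucose;
    PNGase A cleaves regardless.  A glycan with core13fucose == 'yes' is
    therefore seen only in PNGase A digests, everything else in both.
    """
    if core.core13fucose == "yes":
        return RELEASED_BY_A_ONLY
    return RELEASED_BY_F_AND_A
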