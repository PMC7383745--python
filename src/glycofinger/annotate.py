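"""MS1 peak annotation: recalibration, mass decomposition, ladder detection.

The assignment problem is the one a glycomics expert solves by eye on a
reflectron MALDI spectrum of released, reducing N-glycans: each [M+Na]+
peak is matched against all residue compositions within a bounded box
whose sodiated m/z falls inside a tolerance window.  Oligomannosidic
glycans (Hex5-9 HexNAc2) double as internal calibrants, so a linear
recalibration against them precedes annotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .mass import (
    MONOISOTOPIC,
    GlycanComposition,
    MassConstants,
    ion_mz,
)
from .spectrum import Peak, Spectrum

__all__ = [
    "DEFAULT_TOLERANCE",
    "COARSE_TOLERANCE",
    "DEFAULT_INTENSITY_FLOOR",
    "CompositionBounds",
    "DEFAULT_BOUNDS",
    "CompositionAssignment",
    "MethylLadder",
    "oligomannose_anchors",
    "recalibrate",
    "decompose_mass",
    "annotate_spectrum",
    "detect_methyl_ladder",
    "max_oligomannose_methylation",
    "assignments_to_records",
    "assignments_to_json",
    "assignments_to_tsv",
]

#: post-recalibration MS1 match window, Da
DEFAULT_TOLERANCE = 0.15
#: pre-calibration anchor search window, Da
COARSE_TOLERANCE = 0.5
#: fraction of base-peak intensity below which peaks are ignored
DEFAULT_INTENSITY_FLOOR = 0.01
#: anchor residuals after a successful recalibration must fall below this
FINE_TOLERANCE = 0.02


@dataclass(frozen=True)
class CompositionBounds:
    """Per-residue search box for mass decomposition.

    The defaults cover every composition reported for the thirteen
    fingerprint groups, including the large os[10]213-class glycans, while
    enforcing the chitobiose core (HexNAc >= 2).
    """

    hex: tuple[int, int] = (0, 12)
    hexnac: tuple[int, int] = (2, 4)
    pen: tuple[int, int] = (0, 4)
    me: tuple[int, int] = (0, 8)

    def iter_compositions(self):
        for h in range(self.hex[0], self.hex[1] + 1):
            for n in range(self.hexnac[0], self.hexnac[1] + 1):
                for p in range(self.pen[0], self.pen[1] + 1):
                    for m in range(self.me[0], self.me[1] + 1):
                        yield GlycanComposition(h, n, p, m)


DEFAULT_BOUNDS = CompositionBounds()


@dataclass(frozen=True)
class CompositionAssignment:
    """Ranked candidate compositions for one peak.

    Candidates are (composition, absolute error in Da, error in ppm),
    sorted by |error| then total residue count then lexicographic counts.
    ``chosen`` indexes the accepted candidate (0 = top ranked) or is None
    when no composition fits.  ``is_anchor`` marks oligomannosidic
    (internal-calibrant class) assignments.
    """

    peak: Peak
    candidates: tuple[tuple[GlycanComposition, float, float], ...]
    chosen: int | None = None
    is_anchor: bool = False

    @property
    def composition(self) -> GlycanComposition | None:
        if self.chosen is None:
            return None
        return self.candidates[self.chosen][0]


def oligomannose_anchors(lo: int = 5, hi: int = 9) -> tuple[GlycanComposition, ...]:
    """Oligomannosidic internal-calibrant compositions (default Man5-Man9)."""
    return tuple(GlycanComposition(n_hex=h, n_hexnac=2) for h in range(lo, hi + 1))


def recalibrate(s: Spectrum, anchors=None, coarse_tol: float = COARSE_TOLERANCE,
                constants: MassConstants = MONOISOTOPIC) -> Spectrum:
    """Linear internal recalibration against oligomannosidic anchors.

    Each anchor composition is matched to the nearest peak within
    ``coarse_tol``; with at least two matches a least-squares line maps
    observed to theoretical m/z and is applied to every peak.  With fewer
    than two matches the spectrum is returned unchanged, carrying a
    warning.  A successful fit is required to leave anchor residuals no
    worse than before (least squares guarantees this in the 2-norm).
    """
    if anchors is None:
        anchors = oligomannose_anchors()
    theoretical = np.array([ion_mz(a, constants=constants) for a in anchors])
    observed_mzs = np.array([p.mz for p in s.peaks])
    matched_obs, matched_theo = [], []
    for t in theoretical:
        if observed_mzs.size == 0:
            break
        i = int(np.argmin(np.abs(observed_mzs - t)))
        if abs(observed_mzs[i] - t) <= coarse_tol:
            matched_obs.append(observed_mzs[i])
            matched_theo.append(t)
    if len(matched_obs) < 2:
        return s.with_warning(
            f"recalibration skipped: only {len(matched_obs)} anchor(s) matched"
        )
    slope, offset = np.polyfit(matched_obs, matched_theo, 1)
    corrected = s.with_peaks(
        (Peak(slope * p.mz + offset, p.intensity) for p in s.peaks),
        calibrated=True,
        calibration=(float(slope), float(offset)),
    )
    return corrected


def decompose_mass(mz: float, tol: float = DEFAULT_TOLERANCE,
                   bounds: CompositionBounds = DEFAULT_BOUNDS,
                   constants: MassConstants = MONOISOTOPIC,
                   ) -> list[tuple[GlycanComposition, float, float]]:
    """All compositions in the bound box whose sodiated m/z is within tol.

    Returns (composition, error_da, error_ppm) tuples where error is
    observed minus theoretical, sorted by |error|, then total residue
    count (simpler first), then lexicographic counts.  Compositions are
    reported in folded (Pen+Me) canonical form; any dHex-containing
    structure is an isobaric alias of a folded entry.  An empty list means
    the peak is unassigned, which is a valid outcome.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    base = constants.water + constants.sodium_cation
    out = []
    for h in range(bounds.hex[0], bounds.hex[1] + 1):
        mh = base + h * constants.hex
        if mh - mz > tol:
            break
        for n in range(bounds.hexnac[0], bounds.hexnac[1] + 1):
            mn = mh + n * constants.hexnac
            if mn - mz > tol:
                break
            for p in range(bounds.pen[0], bounds.pen[1] + 1):
                mp = mn + p * constants.pen
                if mp - mz > tol:
                    break
                for m in range(bounds.me[0], bounds.me[1] + 1):
                    mm = mp + m * constants.me
                    if mm - mz > tol:
                        break
                    err = mz - mm
                    if abs(err) <= tol:
                        c = GlycanComposition(h, n, p, m)
                        out.append((c, err, 1e6 * err / mz))
    out.sort(key=lambda t: (abs(t[1]), t[0].total_residues,
                            (t[0].n_hex, t[0].n_hexnac, t[0].n_pen, t[0].n_me)))
    return out


def annotate_spectrum(s: Spectrum, tol: float = DEFAULT_TOLERANCE,
                      intensity_floor: float = DEFAULT_INTENSITY_FLOOR,
                      bounds: CompositionBounds = DEFAULT_BOUNDS,
                      constants: MassConstants = MONOISOTOPIC,
                      require_calibrated: bool = False,
                      ) -> list[CompositionAssignment]:
    """Assign compositions to every MS1 peak above the intensity floor.

    One assignment record per retained peak, in ascending m/z order.
    Oligomannosidic top candidates are flagged as the anchor class.  By
    default an uncalibrated spectrum is annotated anyway (the caller
    waives calibration); set ``require_calibrated`` to insist.
    """
    if s.level != "MS1":
        raise ValueError("annotate_spectrum expects an MS1 spectrum")
    if require_calibrated and not s.calibrated:
        raise ValueError("spectrum is not calibrated (run recalibrate first)")
    floor = intensity_floor * s.base_peak_intensity
    out = []
    for peak in s.peaks:
        if peak.intensity < floor:
            continue
        candidates = tuple(decompose_mass(peak.mz, tol=tol, bounds=bounds,
                                          constants=constants))
        chosen = 0 if candidates else None
        anchor = bool(candidates) and candidates[0][0].is_oligomannosidic
        out.append(CompositionAssignment(peak=peak, candidates=candidates,
                                         chosen=chosen, is_anchor=anchor))
    return out


@dataclass(frozen=True)
class MethylLadder:
    """A run of assigned peaks differing only by consecutive Me counts."""

    base: GlycanComposition          # member with the lowest Me count
    members: tuple[CompositionAssignment, ...]
    me_counts: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.members)

    @property
    def max_me(self) -> int:
        return self.me_counts[-1]

    @property
    def top(self) -> GlycanComposition:
        return self.members[-1].composition

    @property
    def on_oligomannose(self) -> bool:
        return (self.base.n_hexnac == 2 and self.base.n_pen == 0
                and self.base.n_dhex == 0)


def detect_methyl_ladder(assignments) -> list[MethylLadder]:
    """Group assignments into 14-Da methylation ladders.

    Peaks whose chosen compositions share (Hex, HexNAc, Pen) counts and
    carry consecutive Me counts form one ladder (length >= 2).  Ladders
    are reported in ascending order of the base composition.
    """
    by_skeleton: dict[tuple[int, int, int], dict[int, CompositionAssignment]] = {}
    for a in assignments:
        c = a.composition
        if c is None:
            continue
        c = c.fold_dhex()
        by_skeleton.setdefault((c.n_hex, c.n_hexnac, c.n_pen), {})[c.n_me] = a
    ladders = []
    for skeleton in sorted(by_skeleton):
        me_map = by_skeleton[skeleton]
        mes = sorted(me_map)
        run: list[int] = []
        for me in mes + [None]:
            if run and (me is None or me != run[-1] + 1):
                if len(run) >= 2:
                    members = tuple(me_map[k] for k in run)
                    ladders.append(MethylLadder(
                        base=members[0].composition.fold_dhex(),
                        members=members, me_counts=tuple(run)))
                run = []
            if me is not None:
                run.append(me)
    return ladders


def max_oligomannose_methylation(assignments, any_candidate: bool = True) -> int:
    """Largest Me count assigned on an oligomannosidic (HexNAc2, Pen0) skeleton.

    This is the per-spectrum statistic that separates the weakly
    methylated fingerprints (up to three methyl groups per oligomannosidic
    glycan) from the heavily methylated ones (up to seven).

    By default every candidate within tolerance is considered, not only
    the top-ranked one: 3 Hex + 3 Me and 4 Pen differ by only 0.036 Da, so
    a methylated oligomannosidic peak is frequently isobaric with a
    pentose-rich alternative that |error| ranking may prefer.  An expert
    reads such peaks through the 14-Da ladder they sit in; accepting the
    oligomannosidic interpretation whenever it fits the window mirrors
    that.  Set ``any_candidate=False`` to use only the chosen candidate.
    """
    best = 0
    for a in assignments:
        if any_candidate:
            pool = [c for c, _, _ in a.candidates]
        else:
            pool = [a.composition] if a.composition is not None else []
        for c in pool:
            c = c.fold_dhex()
            if c.n_hexnac == 2 and c.n_pen == 0 and c.n_hex >= 5:
                best = max(best, c.n_me)
    return best


def assignments_to_records(assignments) -> list[dict]:
    records = []
    for a in assignments:
        rec = {
            "mz": a.peak.mz,
            "intensity": a.peak.intensity,
            "os": a.composition.os_code if a.composition is not None else None,
            "error_da": a.candidates[a.chosen][1] if a.chosen is not None else None,
            "error_ppm": a.candidates[a.chosen][2] if a.chosen is not None else None,
            "n_candidates": len(a.candidates),
            "anchor": a.is_anchor,
        }
        records.append(rec)
    return records


def assignments_to_json(assignments, fh) -> None:
    json.dump({"assignments": assignments_to_records(assignments)}, fh, indent=2)
    fh.write("\n")


def assignments_to_tsv(assignments, fh) -> None:
    cols = ["mz", "intensity", "os", "error_da", "error_ppm", "n_candidates", "anchor"]
    fh.write("\t".join(cols) + "\n")
    for rec in assignments_to_records(assignments):
        fh.write("\t".join("" if rec[c] is None else str(rec[c]) for c in cols) + "\n")
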