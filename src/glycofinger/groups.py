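"""Rule-based classification of annotated MS1 spectra into glyco-groups.

Thirteen named MALDI fingerprint classes (Kei, Hel, Jos, Ori, Raa, Now,
Sun, Sol, Jar, Gov, Ama, Asp, Pit) are described by diagnostic masses
(required, supporting, forbidden), an oligomannose-methylation trait and
ladder rules.  A spectrum is scored against every profile; the winner is
reported unless no profile reaches the orphan threshold.  Several groups
are not separable on MS1 masses alone (isobaric fingerprints split only
by methylation degree, one marker peak, or relative dominance); those
pairs are documented by :func:`confusability_report` and
:func:`documented_confusable_pairs`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import yaml

from .annotate import (
    DEFAULT_INTENSITY_FLOOR,
    DEFAULT_TOLERANCE,
    max_oligomannose_methylation,
)
from .mass import GlycanComposition, ion_mz, parse_os_code

__all__ = [
    "GROUP_NAMES",
    "DOMINANCE_THRESHOLD",
    "ORPHAN_THRESHOLD",
    "MIXTURE_THRESHOLD",
    "ORPHAN",
    "GroupDiagnostic",
    "LadderRule",
    "GlycoGroupProfile",
    "ClassificationResult",
    "builtin_registry",
    "load_registry",
    "classify",
    "confusability_report",
    "documented_confusable_pairs",
]

GROUP_NAMES = ("Kei", "Hel", "Jos", "Ori", "Raa", "Now", "Sun",
               "Sol", "Jar", "Gov", "Ama", "Asp", "Pit")

#: a "dominant" diagnostic must reach this fraction of the base peak
DOMINANCE_THRESHOLD = 0.25
#: best score below this -> orphan pattern
ORPHAN_THRESHOLD = 0.5
#: second-best score above this (with unexplained evidence) -> mixture flag
MIXTURE_THRESHOLD = 0.35

ORPHAN = "orphan"

#: printed diagnostic masses must agree with the mass calculus to this, Da
_REGISTRY_MASS_TOLERANCE = 0.05

#: methylation classes over the max Me count on oligomannosidic glycans
_METHYLATION_CLASSES = {"none": (0, 0), "low": (1, 3), "high": (4, 7)}


@dataclass(frozen=True)
class GroupDiagnostic:
    """One diagnostic mass: printed m/z, composition, dominance requirement."""

    mz: float                      # printed value, for reports
    composition: GlycanComposition
    dominant: bool = False

    @property
    def theoretical_mz(self) -> float:
        return ion_mz(self.composition)

    @property
    def os(self) -> str:
        return self.composition.os_code


@dataclass(frozen=True)
class LadderRule:
    """A 14-Da methylation ladder attached to a diagnostic composition."""

    base: GlycanComposition
    direction: str  # "up" (adding Me) or "down" (removing Me)
    steps: int


@dataclass(frozen=True)
class GlycoGroupProfile:
    name: str
    required: tuple[GroupDiagnostic, ...]
    supporting: tuple[GroupDiagnostic, ...] = ()
    forbidden: tuple[GroupDiagnostic, ...] = ()
    oligomannose_methylation: str | None = None
    ladders: tuple[LadderRule, ...] = ()
    notes: str = ""

    def __post_init__(self):
        req = {d.composition for d in self.required}
        forb = {d.composition for d in self.forbidden}
        if req & forb:
            raise ValueError(f"{self.name}: required and forbidden overlap")
        if self.oligomannose_methylation is not None \
                and self.oligomannose_methylation not in _METHYLATION_CLASSES:
            raise ValueError(
                f"{self.name}: unknown methylation class "
                f"{self.oligomannose_methylation!r}")
        for d in self.required + self.supporting + self.forbidden:
            if abs(d.mz - d.theoretical_mz) > _REGISTRY_MASS_TOLERANCE:
                raise ValueError(
                    f"{self.name}: printed m/z {d.mz} disagrees with computed "
                    f"{d.theoretical_mz:.2f} for {d.os}")

    def diagnostic_masses(self) -> set[float]:
        """Theoretical m/z of required plus supporting diagnostics."""
        return {d.theoretical_mz for d in self.required + self.supporting}


def _parse_diagnostic(entry: dict) -> GroupDiagnostic:
    return GroupDiagnostic(mz=float(entry["mz"]),
                           composition=parse_os_code(str(entry["os"])),
                           dominant=bool(entry.get("dominant", False)))


def load_registry(source) -> tuple[GlycoGroupProfile, ...]:
    """Load a profile registry from a YAML path or open handle."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    profiles = []
    for g in doc["groups"]:
        profiles.append(GlycoGroupProfile(
            name=g["name"],
            required=tuple(_parse_diagnostic(d) for d in g.get("required", [])),
            supporting=tuple(_parse_diagnostic(d) for d in g.get("supporting", [])),
            forbidden=tuple(_parse_diagnostic(d) for d in g.get("forbidden", [])),
            oligomannose_methylation=g.get("oligomannose_methylation"),
            ladders=tuple(LadderRule(base=parse_os_code(l["base"]),
                                     direction=l["direction"],
                                     steps=int(l["steps"]))
                          for l in g.get("ladders", [])),
            notes=g.get("notes", "").strip(),
        ))
    return tuple(profiles)


@lru_cache(maxsize=1)
def builtin_registry() -> tuple[GlycoGroupProfile, ...]:
    """The packaged, versioned registry of the thirteen glyco-groups."""
    ref = resources.files("glycofinger.data") / "glyco_groups.yaml"
    with ref.open() as fh:
        return load_registry(fh)


def methylation_class(max_me: int) -> str:
    """Map an observed maximum oligomannose Me count to a trait class."""
    if max_me == 0:
        return "none"
    if max_me <= 3:
        return "low"
    return "high"


@dataclass(frozen=True)
class ClassificationResult:
    scores: dict
    best: str
    evidence: dict = field(compare=False)
    mixture_flag: bool = False
    runner_up: str | None = None

    @property
    def is_orphan(self) -> bool:
        return self.best == ORPHAN


def _peak_intensity_near(assignments, mz: float, tol: float) -> float:
    """Largest intensity among peaks within tol of mz (0 if none)."""
    return max((a.peak.intensity for a in assignments
                if abs(a.peak.mz - mz) <= tol), default=0.0)


def classify(assignments, ladders=None, registry=None,
             tol: float = DEFAULT_TOLERANCE,
             dominance_threshold: float = DOMINANCE_THRESHOLD,
             intensity_floor: float = DEFAULT_INTENSITY_FLOOR,
             orphan_threshold: float = ORPHAN_THRESHOLD,
             mixture_threshold: float = MIXTURE_THRESHOLD) -> ClassificationResult:
    """Score an annotated MS1 spectrum against every glyco-group profile.

    Each group's score is the weighted fraction of its diagnostics that
    are satisfied: required masses weigh 2 (a "dominant" one must reach
    the dominance threshold), supporting masses weigh 1, and a declared
    oligomannose-methylation class weighs 1.  A forbidden mass present
    above the dominance threshold zeroes the group.  Scores are invariant
    under uniform intensity rescaling.

    The best-scoring group wins unless its score falls below the orphan
    threshold.  The mixture flag is raised when the runner-up scores above
    the mixture threshold *and* its matched diagnostics are not merely a
    subset of the winner's own masses - i.e. there is evidence the winner
    cannot explain, as expected for blended commercial material.
    """
    if registry is None:
        registry = builtin_registry()
    base = max((a.peak.intensity for a in assignments), default=0.0)
    if ladders is not None:
        me_counts = [l.max_me for l in ladders if l.on_oligomannose]
        observed_max_me = max(me_counts, default=0)
        # singleton methylated oligomannose peaks are not part of any ladder
        observed_max_me = max(observed_max_me,
                              max_oligomannose_methylation(assignments))
    else:
        observed_max_me = max_oligomannose_methylation(assignments)
    observed_meth = methylation_class(observed_max_me)

    scores: dict[str, float] = {}
    evidence: dict[str, dict] = {}
    matched_masses: dict[str, set[float]] = {}
    required_weight: dict[str, float] = {}
    for profile in registry:
        matched, missing, violated = [], [], []
        got = 0.0
        total = 0.0
        req_got = 0.0
        masses_hit: set[float] = set()
        for diag, weight in ([(d, 2.0) for d in profile.required]
                             + [(d, 1.0) for d in profile.supporting]):
            total += weight
            intensity = _peak_intensity_near(assignments, diag.theoretical_mz, tol)
            need = dominance_threshold if diag.dominant else intensity_floor
            if base > 0 and intensity >= need * base:
                got += weight
                if weight == 2.0:
                    req_got += weight
                matched.append(diag)
                masses_hit.add(diag.theoretical_mz)
            else:
                missing.append(diag)
        if profile.oligomannose_methylation is not None:
            total += 1.0
            if observed_meth == profile.oligomannose_methylation:
                got += 1.0
            else:
                missing.append(f"oligomannose methylation "
                               f"{profile.oligomannose_methylation} "
                               f"(observed {observed_meth})")
        for diag in profile.forbidden:
            intensity = _peak_intensity_near(assignments, diag.theoretical_mz, tol)
            if base > 0 and intensity >= dominance_threshold * base:
                violated.append(diag)
        score = 0.0 if violated else (got / total if total else 0.0)
        scores[profile.name] = score
        matched_masses[profile.name] = masses_hit
        required_weight[profile.name] = 0.0 if violated else req_got
        evidence[profile.name] = {
            "matched": matched, "missing": missing, "violated": violated,
            "observed_methylation": observed_meth,
        }

    # ties on score go to the profile with more matched required evidence
    # (the more specific fingerprint), then alphabetically for determinism
    ranking = sorted(scores, key=lambda n: (-scores[n], -required_weight[n], n))
    best = ranking[0] if scores and scores[ranking[0]] >= orphan_threshold else ORPHAN
    runner_up = ranking[1] if len(ranking) > 1 else None
    mixture = False
    if best != ORPHAN and runner_up is not None \
            and scores[runner_up] >= mixture_threshold:
        best_profile = next(p for p in registry if p.name == best)
        explained = best_profile.diagnostic_masses()
        extra = {m for m in matched_masses[runner_up]
                 if min((abs(m - e) for e in explained), default=1e9) > tol}
        mixture = bool(extra)
    return ClassificationResult(scores=scores, best=best, evidence=evidence,
                                mixture_flag=mixture, runner_up=runner_up)


def confusability_report(registry=None, mass_tol: float = _REGISTRY_MASS_TOLERANCE):
    """Pairwise overlap of diagnostic mass sets across the registry.

    Returns ``(overlap, flagged)`` where ``overlap[a][b]`` counts shared
    required+supporting masses and ``flagged`` lists pairs that MS1 masses
    alone cannot separate, with the reason: an identical required set
    (split only by the oligomannose-methylation trait), a single
    distinguishing marker mass, or a required mass of one group occurring
    in the other's profile (separation by relative dominance only).
    """
    if registry is None:
        registry = builtin_registry()

    def massset(diags):
        return {round(d.theoretical_mz, 2) for d in diags}

    overlap: dict[str, dict[str, int]] = {}
    flagged: list[tuple[str, str, str]] = []
    for i, a in enumerate(registry):
        overlap[a.name] = {}
        a_all = massset(a.required) | massset(a.supporting)
        for b in registry:
            b_all = massset(b.required) | massset(b.supporting)
            overlap[a.name][b.name] = len(a_all & b_all)
        for b in registry[i + 1:]:
            req_a, req_b = massset(a.required), massset(b.required)
            b_all = massset(b.required) | massset(b.supporting)
            diff = req_a ^ req_b
            if req_a == req_b:
                if a.oligomannose_methylation != b.oligomannose_methylation:
                    flagged.append((a.name, b.name, "oligomannose methylation"))
                else:
                    flagged.append((a.name, b.name, "identical diagnostics"))
            elif len(diff) == 1:
                flagged.append((a.name, b.name,
                                f"presence of m/z {next(iter(diff))}"))
            elif req_a & b_all or req_b & a_all:
                flagged.append((a.name, b.name, "relative dominance of shared masses"))
    return overlap, flagged


def documented_confusable_pairs(registry=None) -> set[frozenset]:
    """Group pairs between which MS1 misassignment is expected and documented."""
    _, flagged = confusability_report(registry)
    return {frozenset((a, b)) for a, b, _ in flagged}
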