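# Methods

## Mass model

A glycan is represented at composition level only: counts over
{Hex, HexNAc, Pen, Me, dHex}.  Residue masses are monoisotopic,
dehydrated monomers (Da):

| residue | mass | note |
|---|---|---|
| Hex | 162.05282 | C₆H₁₀O₅ |
| HexNAc | 203.07937 | C₈H₁₃NO₅ |
| Pen | 132.04226 | C₅H₈O₄ |
| Me | 14.01565 | CH₂ increment |
| dHex | 146.05791 | ≡ Pen + Me exactly (C₆H₁₀O₄) |
| water | 18.01056 | one per free oligosaccharide |
| Na⁺ | 22.98922 | electron-corrected |
| H⁺ | 1.00728 | |

The neutral mass is the residue sum plus one water; the MALDI default ion
is the singly sodiated, underivatized reducing glycan.  Reduction
(alditol) adds two hydrogen atoms before the adduct; charge *z* divides
by *z* after adding *z* carriers.  Constants are fixed to five decimals
and exported as versioned JSON so every reported m/z is traceable; this
set reproduces the conventionally printed reflectron MALDI values at
their printed precision (one printed outlier, 2565.7 for os[12]213,
disagrees with the arithmetic implied by all other values — computed
2565.9 — and is excluded from diagnostics).

Because dHex and Pen+Me are isoelemental, MS1 cannot distinguish them;
all MS1-facing code reports the folded (Pen+Me) canonical form, and
`n_dhex` is kept separate only where the deoxyhexose is actually known
(the in-silico fucosyltransferase).  A methyl group is modeled as a mass
increment on the composition — which residue carries it is a
structure-level question outside MS.  The N-glycan validity condition
(HexNAc ≥ 2, the chitobiose core) is enforced by fragment enumeration
and annotation bounds, not by generic mass arithmetic.

The in-silico core α1,6-fucosyltransferase models the substrate test
used on the Man5Gn marker: it requires an antennary GlcNAc (HexNAc ≥ 3)
and an unfucosylated core, transfers exactly one dHex, and shifts the
mass by 146.05791 Da.  The release rule maps core 1,3-fucosylated
evidence to "PNGase A only", everything else to "PNGase F and A".

## MS1 annotation

* **Recalibration.** Oligomannosidic glycans Man5–Man9 (Hex₅₋₉HexNAc₂)
  act as internal standards.  Each anchor is matched to the nearest peak
  within a coarse 0.5 Da window; with ≥ 2 matches a least-squares line
  maps observed to theoretical m/z and is applied to all peaks (the
  2-norm of anchor residuals cannot increase).  With < 2 matches the
  spectrum is returned unchanged with a warning.
* **Decomposition.** Peaks are matched against every composition in a
  bounded box (Hex ≤ 12, HexNAc 2–4, Pen ≤ 4, Me ≤ 8 — covering all
  reported compositions) whose sodiated m/z lies within the tolerance.
  Default tolerance is 0.15 Da after recalibration; the printed values
  this models agree to ~0.1 Da.  Candidates are ranked by |error|, then
  total residue count (simpler first), then lexicographic counts; output
  order is deterministic and tolerance-monotone.  An unassignable peak
  is a valid outcome, not an error.
* **Intensity floor.** Peaks below 1% of the base peak are ignored; no
  instrument threshold is reported anywhere, so this is an engineering
  default (configurable).
* **Ladders.** Assigned peaks sharing (Hex, HexNAc, Pen) and consecutive
  Me counts form 14-Da methylation ladders.  The per-spectrum maximum Me
  on an oligomannosidic skeleton is the trait separating weakly
  (≤ 3 Me) from heavily (≤ 7 Me) methylated fingerprints.
* **A genuine isobaric family.** 4 Pen and 3 Hex + 3 Me differ by only
  0.036 Da, far below MALDI accuracy at these masses, so a methylated
  oligomannosidic peak (e.g. Man5+4Me) is frequently isobaric with a
  pentose-rich alternative that |error| ranking may prefer under noise.
  An expert resolves such peaks through the ladder they sit in; the
  methylation statistic therefore accepts the oligomannosidic
  interpretation whenever it fits the candidate window, and recovery of
  generating compositions is reported per candidate window by default
  (`annotation_recovery(mode="candidates")`), with a strict top-ranked
  mode available.

## MS2 (LIFT) inference

Every composition bipartition yields a complementary pair with
m(y) = residues + water + Na and m(b) = residues + Na, so that
m(b) + m(y) = precursor m/z + m(Na) exactly.  Internal (by) ions share
the b arithmetic and are enumerated but unused by inference.  Four
diagnostic neutral losses are tracked: −221.09 (free reducing GlcNAc),
−203.08 (second GlcNAc), −217.09 (methylated GlcNAc), −146.06 (dHex).
Matching tolerance defaults to 0.3 Da (LIFT values deviate up to ~0.3
from theory).  A loss ion and the b ion of its complement are
numerically identical; both hypotheses are reported for such peaks.

Inference applies four ordered rules, never guessing (absent evidence
stays "unknown", and accumulating evidence never flips a yes to a no):

1. A direct −221.09 loss ⇒ GlcNAc-1 unsubstituted, no core 1,3-fucose.
2. Consecutive −221.09 then −203.08 (or −217.09) ⇒ chitobiose
   unsubstituted (hence GlcNAc-2 bare); a −217.09 variant additionally
   sets the methylated-HexNAc flag.
3. If no reducing-side fragment ever loses both core GlcNAcs while a
   complementary y/b pair splits the molecule exactly at the chitobiose
   (the y ion retaining the two core HexNAc plus at least one further
   residue) ⇒ GlcNAc-2 carries a substituent.  "Lacking both core
   GlcNAcs" is operationalized as a y/loss ion retaining no HexNAc, or
   an explicit second-GlcNAc loss; the complement of a −221.09 loss
   still holds GlcNAc-2 and does not count.
4. If −221.09 never occurs directly but only after −146.06 ⇒ core
   1,3-linked fucose on GlcNAc-1.

Rules are composition-level; linkage positions and which residue is
methylated are NMR territory and out of scope.  One reported loss of
"211.1" for a free reducing GlcNAc is treated as the 221.09 rule (the
arithmetic admits no 211 loss; a typo is assumed).

## Fingerprint registry and classification

The packaged YAML registry holds exactly 13 profiles; each diagnostic
carries its printed m/z and os code, and the loader verifies printed
against computed mass to 0.05 Da.  A tentative 14th pattern ('Wel', a
possible split-off of 'Jos') is profile metadata only; the heterogeneity
of 'Ori' is handled by the mixture flag rather than extra groups.

Scoring: required masses weigh 2 (a "dominant" diagnostic must reach
25% of base-peak intensity; "present" means above the 1% floor),
supporting masses weigh 1, a declared oligomannose-methylation class
(none = 0, low = 1–3, high = 4–7 Me) weighs 1; any forbidden mass above
the dominance threshold zeroes the group.  The score is the matched
fraction of total weight, invariant under uniform intensity rescaling.
No dominance quantification is reported for the real spectra, so the
25% threshold is chosen to make the published pattern descriptions
classify cleanly.  Ties go to the profile with more matched required
evidence (the more specific fingerprint), then alphabetically.

The best group wins unless its score is below the orphan threshold
(0.5).  The mixture flag fires when the runner-up scores ≥ 0.35 *and*
matched at least one diagnostic mass the winner's own profile does not
contain — high runner-up scores among the documented confusable
families (e.g. the Jar subtypes) are expected for pure material and are
not mixture evidence.

`confusability_report()` documents which groups MS1 masses cannot
separate: identical required sets split only by methylation (Raa/Now;
Jar/Gov/Ama), a single marker mass (Sol vs the Jar family differ only by
Man5Gn at 1460.5), or shared dominant masses separable only by relative
abundance (Hel/Jos, Jos/Ori).  On the synthetic benchmark all residual
misclassifications fall inside these pairs.

## Synthetic data

The generator asserts only the ordinal intensity structure of real
fingerprint spectra (no intensity tables exist to emulate): dominant
diagnostics 100, present-level required 40, supporting 30,
oligomannosidic anchors 15, ladder decay ×0.6 per step.  Methylation
ladders ride on Man5 and Man6 (keeping spectra compact while carrying
the full 1–7 Me trait).  Mass error is Gaussian in ppm (benchmark
default σ = 50 ppm) applied before a linear calibration drift;
intensities get log-normal scatter (σ = 0.3); decoys are drawn uniformly
on [900, 2600] Da excluding ±1 Da around any composition in the search
box; contamination overlays a second group's template at a given
fraction.  Each spectrum uses a PRNG stream derived from (seed, index),
so subsets reproduce exactly.

MS2 spectra are generated from a core-evidence specification and emit
exactly the fragments the rules need (e.g. the reducing-GlcNAc loss
appears only after the dHex loss when core fucose is claimed);
contradictory specifications are rejected.  At zero noise both loops
close exactly: annotation recovers 100% of truth peaks top-ranked, and
core inference reproduces all four archetypes.

What passing these tests does *not* show about real data: real MALDI
spectra have isotope envelopes, detector saturation, matrix clusters,
continuous baselines and peak-picking artifacts, none of which are
modeled; real intensity ratios vary biologically; and the registry's
supporting-mass sets for the rarer groups are extensible stubs awaiting
more published spectra.

## Tree concordance

Trees are consumed (Newick; bootstrap values as internal labels are
ignored), never inferred.  Unrooted input is midpoint-rooted (missing
edge lengths treated as unit; if the midpoint degenerately coincides
with a leaf node, the as-read basal node is kept as root).  A group is
monophyletic when the labeled leaves under its MRCA are exactly its own
— unlabeled leaves (outgroups, references) are ignored — paraphyletic
when instead its labeled complement forms a clade, else polyphyletic;
single-leaf groups are trivially monophyletic.  Concordance is the
fraction of monophyletic groups.  No numeric concordance is published
to target, so the statistic is validated by construction: on simulated
group-block backbones it is 1.0 and decreases monotonically with the
rate of randomly grafted, randomly labeled noise leaves.

## Problem sizes

Defaults used by the test suite and benchmark: 50 spectra per group at
50 ppm for classifier recovery; 2–5 spectra per group for round-trip and
recovery curves; 60–100 simulated trees per mixing rate; 50 random
masses for the decomposition oracle.  The whole suite runs in a few
seconds on one CPU.

## Known limitations

* Composition assignment is blind to isomerism; PGC retention and
  monosaccharide chemistry (which the survey used to split isobaric
  structures) are metadata outside this package.
* Fragment scoring ignores intensities and cross-ring (A/X) ions.
* The classifier is rule-based by design: no intensity-profile learning,
  and MS2 evidence informs core inference, not the group score.
* Doubly charged ESI adduct arithmetic is supported generically, but no
  ESI-specific calibration or ammonium-adduct modeling is included.
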