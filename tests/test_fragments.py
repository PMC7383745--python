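"""Fragment enumeration, LIFT matching and chitobiose-core inference."""

import itertools

import pytest

from glycofinger import (
    CoreEvidence,
    GlycanComposition,
    MONOISOTOPIC,
    Peak,
    RELEASED_BY_A_ONLY,
    RELEASED_BY_F_AND_A,
    SimulationConfig,
    Spectrum,
    enumerate_fragments,
    infer_core,
    ion_mz,
    match_lift,
    parse_os_code,
    pngase_release,
    simulate_ms2,
)
from glycofinger.simulate import CORE_ARCHETYPES

ZERO_NOISE = dict(mass_noise_ppm=0.0, intensity_lognorm_sigma=0.0,
                  decoy_peak_rate=0)

ARCHETYPE_PRECURSORS = {
    "unsubstituted_chitobiose": "os4223",
    "methylated_hexnac_loss": "os3312",
    "glcnac2_substituted": "os3231",
    "core13_fucose": "os4213",
}


class TestEnumerateFragments:
    def test_complementarity_identity(self):
        for code in ("os3231", "os2221", "os4223"):
            prec = parse_os_code(code)
            prec_mz = ion_mz(prec)
            ions = enumerate_fragments(prec)
            y = {i.retained: i.mz for i in ions if i.kind == "y"}
            b = {i.retained: i.mz for i in ions if i.kind == "b"}
            for retained, y_mz in y.items():
                complement = prec.minus(retained)
                if complement in b:
                    assert y_mz + b[complement] == pytest.approx(
                        prec_mz + MONOISOTOPIC.sodium_cation, abs=1e-9)

    def test_kei_complementary_pair(self):
        ions = {i.label: i.mz for i in enumerate_fragments(parse_os_code("os3231"))}
        assert round(ions["y:os1200"], 1) == 609.2
        assert round(ions["b:os2031"], 1) == 757.2

    def test_raa_pair_and_reducing_loss(self):
        ions = {i.label: i.mz for i in enumerate_fragments(parse_os_code("os2221"))}
        assert round(ions["y:os0210"], 1) == 579.2
        assert round(ions["-1 Gn"], 1) == 828.3

    def test_canonical_neutral_loss_ladder(self):
        prec = parse_os_code("os4213")
        prec_mz = ion_mz(prec)
        ions = {i.label: i.mz for i in enumerate_fragments(prec)}
        assert prec_mz - ions["-1 Gn"] == pytest.approx(221.09, abs=0.005)
        assert prec_mz - ions["-2 Gn"] == pytest.approx(221.09 + 203.08, abs=0.01)
        assert prec_mz - ions["-1 Gn(Me)"] == pytest.approx(217.10, abs=0.005)
        assert prec_mz - ions["-dHex"] == pytest.approx(146.06, abs=0.005)

    def test_count_matches_subset_enumeration(self):
        prec = GlycanComposition(n_hex=1, n_hexnac=2, n_me=1)
        ions = enumerate_fragments(prec)
        subs = [
            GlycanComposition(h, n, 0, m)
            for h, n, m in itertools.product(range(2), range(3), range(2))
        ]
        nonempty = [s for s in subs if s.total_residues > 0]
        proper = [s for s in nonempty if s != prec]
        n_losses = 4  # -1 Gn, -2 Gn, and both methylated variants (Me >= 1)
        assert sum(1 for i in ions if i.kind == "y") == len(nonempty)
        assert sum(1 for i in ions if i.kind == "b") == len(proper)
        assert sum(1 for i in ions if i.kind == "by-internal") == len(proper)
        assert sum(1 for i in ions if i.kind == "neutral-loss") == n_losses

    def test_rejects_non_n_glycan(self):
        with pytest.raises(ValueError):
            enumerate_fragments(GlycanComposition(n_hex=5, n_hexnac=1))


class TestMatchLift:
    def test_self_consistency_on_theoretical_spectrum(self):
        prec = parse_os_code("os4223")
        ions = enumerate_fragments(prec)
        mzs = sorted({round(i.mz, 4) for i in ions})
        s = Spectrum(peaks=tuple(Peak(mz, 10.0) for mz in mzs),
                     level="MS2", precursor_mz=ion_mz(prec))
        result = match_lift(s, prec, tol=0.3)
        assert not result.unmatched_peaks

    def test_decoy_peaks_reported_unmatched(self):
        prec = parse_os_code("os3231")
        decoys = (777.77, 913.13)
        peaks = tuple(Peak(m, 5.0) for m in decoys) + (
            Peak(ion_mz(prec) - 221.09, 50.0),)
        s = Spectrum(peaks=peaks, level="MS2", precursor_mz=ion_mz(prec))
        result = match_lift(s, prec, tol=0.3)
        assert sorted(p.mz for p in result.unmatched_peaks) == sorted(decoys)
        assert "-1 Gn" in result.labels()

    def test_inconsistent_precursor_rejected(self):
        prec = parse_os_code("os3231")
        s = Spectrum(peaks=(Peak(600.0, 1.0),), level="MS2", precursor_mz=1500.0)
        with pytest.raises(ValueError):
            match_lift(s, prec)


class TestInferCore:
    @pytest.mark.parametrize("name", sorted(CORE_ARCHETYPES))
    def test_archetypes_recovered_from_noiseless_spectra(self, name):
        truth = CORE_ARCHETYPES[name]
        prec = parse_os_code(ARCHETYPE_PRECURSORS[name])
        cfg = SimulationConfig(seed=21, **ZERO_NOISE)
        ls = simulate_ms2(prec, truth, cfg)
        core = infer_core(match_lift(ls.spectrum, prec))
        assert core == truth

    def test_empty_match_set_stays_unknown(self):
        prec = parse_os_code("os3231")
        s = Spectrum(peaks=(), level="MS2", precursor_mz=ion_mz(prec))
        core = infer_core(match_lift(s, prec))
        assert core.glcnac1_unsubstituted == "unknown"
        assert core.chitobiose_unsubstituted == "unknown"
        assert core.glcnac2_substituted == "unknown"
        assert core.core13fucose == "unknown"

    def test_removing_evidence_degrades_to_unknown_not_no(self):
        # the Kei-style set minus the split pair loses the GlcNAc-2 claim
        # but keeps the free-GlcNAc-1 claim: evidence only accumulates
        prec = parse_os_code("os3231")
        prec_mz = ion_mz(prec)
        full = (Peak(prec_mz, 20.0), Peak(prec_mz - 221.09, 60.0),
                Peak(609.21, 55.0), Peak(757.24, 50.0))
        reduced = full[:2]
        core_full = infer_core(match_lift(
            Spectrum(peaks=full, level="MS2", precursor_mz=prec_mz), prec))
        core_red = infer_core(match_lift(
            Spectrum(peaks=reduced, level="MS2", precursor_mz=prec_mz), prec))
        assert core_full.glcnac2_substituted == "yes"
        assert core_red.glcnac2_substituted == "unknown"
        assert core_full.glcnac1_unsubstituted == "yes"
        assert core_red.glcnac1_unsubstituted == "yes"

    def test_fucose_blocks_direct_reducing_loss(self):
        # 'Ori' style: -221 appears only after -146.06
        prec = parse_os_code("os4213")
        prec_mz = ion_mz(prec)
        peaks = (Peak(prec_mz, 20.0), Peak(prec_mz - 146.06, 60.0),
                 Peak(prec_mz - 146.06 - 221.09, 50.0))
        core = infer_core(match_lift(
            Spectrum(peaks=peaks, level="MS2", precursor_mz=prec_mz), prec))
        assert core.core13fucose == "yes"
        assert core.glcnac1_unsubstituted == "no"

    def test_evidence_invariant_enforced(self):
        with pytest.raises(ValueError):
            CoreEvidence(glcnac1_unsubstituted="no",
                         chitobiose_unsubstituted="yes")


class TestPngaseRelease:
    def test_core_fucose_released_by_a_only(self):
        core = CoreEvidence(core13fucose="yes", glcnac1_unsubstituted="no")
        assert pngase_release(core) == RELEASED_BY_A_ONLY

    def test_no_fucose_released_by_both(self):
        assert pngase_release(CoreEvidence(core13fucose="no")) == RELEASED_BY_F_AND_A
        assert pngase_release(CoreEvidence()) == RELEASED_BY_F_AND_A

    def test_isobaric_glycans_can_differ_in_release_class(self):
        # an MMXF3-like core (1,3-fucosylated) and an isobaric algal glycan
        # with free GlcNAc-1 separate by enzyme even though masses match
        mmxf_like = CoreEvidence(core13fucose="yes", glcnac1_unsubstituted="no")
        algal = CoreEvidence(core13fucose="no", glcnac1_unsubstituted="yes")
        assert pngase_release(mmxf_like) != pngase_release(algal)
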