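"""MS1 annotation: decomposition oracle, recalibration, ladders."""

import itertools
import random

import numpy as np
import pytest

from glycofinger import (
    CompositionBounds,
    GlycanComposition,
    Peak,
    SimulationConfig,
    Spectrum,
    annotate_spectrum,
    decompose_mass,
    detect_methyl_ladder,
    ion_mz,
    max_oligomannose_methylation,
    oligomannose_anchors,
    parse_os_code,
    read_peaklist,
    recalibrate,
    simulate_ms1,
    write_peaklist,
)


def brute_force_decompose(mz, tol, bounds=CompositionBounds()):
    """Independent oracle: plain nested loops over the full bound box."""
    hits = []
    for h, n, p, m in itertools.product(
            range(bounds.hex[0], bounds.hex[1] + 1),
            range(bounds.hexnac[0], bounds.hexnac[1] + 1),
            range(bounds.pen[0], bounds.pen[1] + 1),
            range(bounds.me[0], bounds.me[1] + 1)):
        c = GlycanComposition(h, n, p, m)
        if abs(ion_mz(c) - mz) <= tol:
            hits.append(c)
    return set(hits)


class TestDecomposeMass:
    @pytest.mark.parametrize("mz,code", [
        (1343.46, "os3231"),
        (1296.5, "os3312"),
        (1269.5, "os4213"),
        (1049.4, "os2221"),
    ])
    def test_printed_peak_yields_printed_composition(self, mz, code):
        found = [c for c, _, _ in decompose_mass(mz, tol=0.15)]
        assert parse_os_code(code) in found

    def test_matches_brute_force_oracle(self):
        rng = random.Random(42)
        for _ in range(50):
            mz = rng.uniform(900.0, 2600.0)
            got = {c for c, _, _ in decompose_mass(mz, tol=0.15)}
            assert got == brute_force_decompose(mz, 0.15)

    def test_tolerance_monotone(self):
        for mz in (1049.4, 1343.46, 2079.7, 1500.123):
            narrow = {c for c, _, _ in decompose_mass(mz, tol=0.05)}
            wide = {c for c, _, _ in decompose_mass(mz, tol=0.3)}
            assert narrow <= wide

    def test_ranked_by_error_then_simplicity(self):
        out = decompose_mass(1343.52, tol=0.4)
        errs = [abs(e) for _, e, _ in out]
        assert errs == sorted(errs)

    def test_empty_result_is_not_an_error(self):
        assert decompose_mass(905.0, tol=0.01) == []

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            decompose_mass(1000.0, tol=0.0)


def _drifted_hel(seed=3, offset=0.15, slope=1 + 2e-5):
    cfg = SimulationConfig(group="Hel", n_spectra=1, mass_noise_ppm=0.0,
                           intensity_lognorm_sigma=0.0, decoy_peak_rate=0,
                           calibration_drift=(offset, slope), seed=seed)
    return simulate_ms1(cfg)[0].spectrum


class TestRecalibration:
    def test_exact_spectrum_gets_identity_correction(self):
        cfg = SimulationConfig(group="Hel", n_spectra=1, mass_noise_ppm=0.0,
                               intensity_lognorm_sigma=0.0, decoy_peak_rate=0,
                               seed=1)
        s = recalibrate(simulate_ms1(cfg)[0].spectrum)
        assert s.calibrated
        slope, offset = s.calibration
        assert slope == pytest.approx(1.0, abs=1e-9)
        assert offset == pytest.approx(0.0, abs=1e-6)

    def test_injected_drift_is_corrected(self):
        s = recalibrate(_drifted_hel())
        anchors = [ion_mz(a) for a in oligomannose_anchors()]
        residuals = [min(abs(p.mz - t) for p in s.peaks) for t in anchors]
        assert max(residuals) < 0.02

    def test_never_degrades_anchor_residuals(self):
        rng = np.random.default_rng(5)
        anchors = [ion_mz(a) for a in oligomannose_anchors()]
        for _ in range(10):
            s0 = _drifted_hel(offset=float(rng.uniform(-0.3, 0.3)),
                              slope=float(1 + rng.uniform(-5e-5, 5e-5)))
            before = sum(min(abs(p.mz - t) for p in s0.peaks) ** 2 for t in anchors)
            s1 = recalibrate(s0)
            after = sum(min(abs(p.mz - t) for p in s1.peaks) ** 2 for t in anchors)
            assert after <= before + 1e-12

    def test_too_few_anchors_returns_input_with_warning(self):
        s = Spectrum(peaks=(Peak(1000.0, 10.0), Peak(1100.0, 5.0)))
        out = recalibrate(s)
        assert not out.calibrated
        assert out.mzs == s.mzs
        assert any("recalibration skipped" in w for w in out.warnings)

    def test_man5_anchor_value(self):
        assert round(ion_mz(oligomannose_anchors()[0]), 2) == 1257.42


class TestAnnotateSpectrum:
    def test_hel_main_peak_assigned(self):
        cfg = SimulationConfig(group="Hel", n_spectra=1, mass_noise_ppm=0.0,
                               intensity_lognorm_sigma=0.0, decoy_peak_rate=0,
                               seed=2)
        ls = simulate_ms1(cfg)[0]
        assignments = annotate_spectrum(ls.spectrum)
        by_code = {a.composition.os_code: a for a in assignments
                   if a.composition is not None}
        assert "os4223" in by_code
        assert abs(by_code["os4223"].peak.mz - 1401.5) < 0.05
        # oligomannosidic assignments are flagged as the anchor class
        assert by_code["os5200"].is_anchor
        assert not by_code["os4223"].is_anchor

    def test_empty_spectrum(self):
        assert annotate_spectrum(Spectrum(peaks=())) == []

    def test_permutation_invariant(self):
        cfg = SimulationConfig(group="Sol", n_spectra=1, seed=9)
        s = simulate_ms1(cfg)[0].spectrum
        shuffled = Spectrum(peaks=tuple(reversed(s.peaks)))
        a1 = [(a.peak.mz, a.composition) for a in annotate_spectrum(s)]
        a2 = [(a.peak.mz, a.composition) for a in annotate_spectrum(shuffled)]
        assert a1 == a2

    def test_requires_ms1(self):
        s = Spectrum(peaks=(Peak(500.0, 1.0),), level="MS2", precursor_mz=1000.0)
        with pytest.raises(ValueError):
            annotate_spectrum(s)

    def test_intensity_floor_drops_weak_peaks(self):
        s = Spectrum(peaks=(Peak(1343.4594, 100.0), Peak(1401.5013, 0.1)))
        assignments = annotate_spectrum(s)
        assert len(assignments) == 1


class TestMethylLadders:
    def _spectrum_of(self, codes, intensity=50.0):
        peaks = tuple(Peak(ion_mz(parse_os_code(c)), intensity) for c in codes)
        return Spectrum(peaks=peaks)

    def test_three_step_ladder_ends_at_os4223(self):
        s = self._spectrum_of(["os4221", "os4222", "os4223"])
        ladders = detect_methyl_ladder(annotate_spectrum(s))
        assert len(ladders) == 1
        (ladder,) = ladders
        assert ladder.length == 3
        assert ladder.base == parse_os_code("os4221")
        assert ladder.top == parse_os_code("os4223")

    def test_no_consecutive_me_means_no_ladder(self):
        s = self._spectrum_of(["os4221", "os4223"])  # Me 1 and 3, gap at 2
        assert detect_methyl_ladder(annotate_spectrum(s)) == []

    def test_ama_oligomannose_ladder_reaches_seven(self):
        cfg = SimulationConfig(group="Ama", n_spectra=1, mass_noise_ppm=0.0,
                               intensity_lognorm_sigma=0.0, decoy_peak_rate=0,
                               seed=4)
        ls = simulate_ms1(cfg)[0]
        assignments = annotate_spectrum(ls.spectrum, intensity_floor=0.0)
        assert max_oligomannose_methylation(assignments) == 7
        ladders = detect_methyl_ladder(assignments)
        oligo = [l for l in ladders if l.on_oligomannose]
        assert oligo and max(l.max_me for l in oligo) == 7


class TestPeaklistIO:
    def test_round_trip(self, tmp_path):
        s = Spectrum(peaks=(Peak(1049.36433, 100.0), Peak(1257.42262, 15.0)))
        path = tmp_path / "spec.txt"
        write_peaklist(s, path)
        back = read_peaklist(path)
        assert back.sample_id == "spec"
        assert [round(p.mz, 5) for p in back.peaks] == [1049.36433, 1257.42262]

    def test_reads_csv_and_header(self, tmp_path):
        path = tmp_path / "spec.csv"
        path.write_text("mz,intensity\n1049.36,100\n1257.42,15\n")
        s = read_peaklist(path)
        assert len(s) == 2

    def test_ms2_requires_precursor(self):
        with pytest.raises(ValueError):
            Spectrum(peaks=(Peak(500.0, 1.0),), level="MS2")
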