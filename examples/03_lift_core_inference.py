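"""Infer chitobiose-core substitution from a LIFT (MS2) peak list.

Builds a noiseless MS2 spectrum for the os3231 precursor carrying the
'Kei'-style evidence (free reducing GlcNAc, substituted GlcNAc-2), then
one for the core-fucosylated os4213, and runs the inference rules.
"""

from glycofinger import (
    SimulationConfig,
    infer_core,
    match_lift,
    parse_os_code,
    pngase_release,
    simulate_ms2,
)
from glycofinger.simulate import CORE_ARCHETYPES

cfg = SimulationConfig(seed=3, mass_noise_ppm=0.0,
                       intensity_lognorm_sigma=0.0, decoy_peak_rate=0)

for archetype, code in (("glcnac2_substituted", "os3231"),
                        ("core13_fucose", "os4213")):
    prec = parse_os_code(code)
    labeled = simulate_ms2(prec, CORE_ARCHETYPES[archetype], cfg)
    result = match_lift(labeled.spectrum, prec)
    core = infer_core(result)
    print(f"precursor {code} ({labeled.spectrum.precursor_mz:.1f}):")
    for key, value in core.as_dict().items():
        print(f"  {key:26s} {value}")
    print(f"  predicted release: {pngase_release(core)}\n")
# For os3231 the -221.09 loss shows a free reducing GlcNAc while the
# complementary 609.2/757.2 pair pins a substituent on GlcNAc-2.  For
# os4213 the reducing GlcNAc leaves only after a 146.06 deoxyhexose loss,
# the signature of core 1,3-fucose - hence release by PNGase A only.
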