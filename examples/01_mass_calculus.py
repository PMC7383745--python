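"""Sodiated masses for glycan compositions and the "os" shorthand.

Builds a few compositions reported for Chlorella products, prints their
[M+Na]+ m/z and demonstrates the deoxyhexose = pentose + methyl folding
and the in-silico core-fucosylation of Man5Gn.
"""

from glycofinger import (
    GlycanComposition,
    add_core_fucose,
    ion_mz,
    parse_os_code,
)

print("composition   [M+Na]+ m/z")
for code in ("os3231", "os4223", "os3312", "os2221", "os[10]213"):
    print(f"  {code:10s}  {ion_mz(parse_os_code(code)):9.2f}")
# Each line is the monoisotopic mass of the sodiated, underivatized
# reducing glycan: e.g. os3231 = Hex3 HexNAc2 Pen3 Me1 gives 1343.46,
# the dominant peak of the 'Kei' fingerprint.

with_dhex = GlycanComposition(n_hex=3, n_hexnac=2, n_pen=2, n_dhex=1)
print(f"\nHex3HexNAc2Pen2dHex1 folds to {with_dhex.os_code} "
      f"(same mass: {ion_mz(with_dhex):.2f})")
# A deoxyhexose and a methylated pentose share one elemental formula, so
# MS1 reports the folded Pen+Me form.

man5gn = GlycanComposition(n_hex=5, n_hexnac=3)
product = add_core_fucose(man5gn)
print(f"\ncore fucosylation: {ion_mz(man5gn):.1f} -> {ion_mz(product):.1f}")
# The 146.06 Da shift reproduces the observed in-vitro conversion of the
# Man5Gn marker peak; plain Man5 (no antennary GlcNAc) is rejected as a
# substrate.
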