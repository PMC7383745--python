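# Diagnostic fingerprint registry for the thirteen Chlorella glyco-groups.
#
# Masses are printed [M+Na]+ values of underivatized reducing glycans; each
# carries its composition code so the loader can verify it against the mass
# calculus (agreement required to 0.05 Da).  "dominant" diagnostics must
# reach the dominance threshold (default 25% of base peak); plain entries
# only need to be present above the intensity floor.
#
# oligomannose_methylation encodes the maximum methylation observed on the
# oligomannosidic (HexNAc2) glycans: none (0), low (1-3), high (4-7);
# null when the trait is not diagnostic for the group.
version: "1.0.0"
groups:
  - name: Kei
    required:
      - {mz: 1343.46, os: os3231, dominant: true}
      - {mz: 1357.5, os: os3232}
    supporting: []
    forbidden:
      - {mz: 1329.4, os: os3230}
      - {mz: 1401.5, os: os4223}
      - {mz: 1197.4, os: os3220}
    oligomannose_methylation: null
    ladders: []
    notes: >
      Dominant os3231 exceeding the land-plant MMXF3 mass by one pentose;
      GlcNAc-1 free, GlcNAc-2 substituted (LIFT evidence).

  - name: Hel
    required:
      - {mz: 1401.5, os: os4223, dominant: true}
    supporting:
      - {mz: 1373.5, os: os4221}
      - {mz: 1387.5, os: os4222}
    forbidden:
      - {mz: 1269.5, os: os4213}
    oligomannose_methylation: null
    ladders:
      - {base: os4223, direction: down, steps: 2}
    notes: >
      Main peak preceded by a 14-Da methylation ladder down to os4221;
      unsubstituted chitobiose core.  Matches C. sorokiniana type strains.

  - name: Jos
    required:
      - {mz: 1373.5, os: os4221, dominant: true}
      - {mz: 1387.5, os: os4222}
    supporting: []
    forbidden:
      - {mz: 1401.5, os: os4223}
      - {mz: 1269.5, os: os4213}
    oligomannose_methylation: null
    ladders: []
    notes: >
      Shares os4221 with 'Hel' but as the dominant peak.  A tentative
      subtype ('Wel', with m/z 1211.3/1414.4/1428.4 and strongly methylated
      oligomannosidic glycans) is kept as metadata, not a 14th group.

  - name: Ori
    required:
      - {mz: 1269.5, os: os4213, dominant: true}
    supporting:
      - {mz: 1373.5, os: os4221}
      - {mz: 1211.4, os: os3221}
    forbidden:
      - {mz: 1401.5, os: os4223}
    oligomannose_methylation: null
    ladders: []
    notes: >
      Dominant os4213 carrying core 1,3-linked fucose (PNGase A only;
      reducing GlcNAc lost only after the 146.06 deoxyhexose loss).
      Heterogeneous group; possible catchment basin for several strains,
      handled by the mixture flag rather than extra groups.

  - name: Raa
    required:
      - {mz: 1049.4, os: os2221, dominant: true}
    supporting: []
    forbidden: []
    oligomannose_methylation: none
    ladders: []
    notes: >
      Dominant os2221 with arabinose on GlcNAc-2; oligomannosidic glycans
      unmethylated.  Matches culture collection strain SAG211-34.

  - name: Now
    required:
      - {mz: 1049.4, os: os2221, dominant: true}
    supporting: []
    forbidden: []
    oligomannose_methylation: low
    ladders: []
    notes: >
      Isobaric with 'Raa' (xylose instead of arabinose on GlcNAc-2);
      separated at MS1 only by methylated oligomannosidic glycans.

  - name: Sun
    required:
      - {mz: 1296.5, os: os3312, dominant: true}
    supporting:
      - {mz: 1003.4, os: os3205}
      - {mz: 1884.7, os: os5332}
    forbidden: []
    oligomannose_methylation: null
    ladders: []
    notes: >
      Third N-acetylhexosamine (4-O-methyl GlcNAc) renders the group
      unique; LIFT shows an unsubstituted chitobiose with a methylated
      HexNAc loss.

  - name: Sol
    required:
      - {mz: 1329.4, os: os3230, dominant: true}
      - {mz: 1197.4, os: os3220}
      - {mz: 1491.5, os: os4230}
      - {mz: 1460.5, os: os5300}
    supporting:
      - {mz: 1343.46, os: os3231}
      - {mz: 1211.4, os: os3221}
    forbidden: []
    oligomannose_methylation: low
    ladders:
      - {base: os3220, direction: up, steps: 2}
    notes: >
      Pentose series os3220/os3230/os4230 with methylation variants plus
      Man5Gn (m/z 1460.5), the substrate of core alpha1,6-fucosyltransferase.

  - name: Jar
    required:
      - {mz: 1329.4, os: os3230, dominant: true}
      - {mz: 1197.4, os: os3220}
      - {mz: 1491.5, os: os4230}
    supporting:
      - {mz: 1343.46, os: os3231}
      - {mz: 1211.4, os: os3221}
    forbidden:
      - {mz: 1460.5, os: os5300}
    oligomannose_methylation: none
    ladders:
      - {base: os3220, direction: up, steps: 2}
    notes: >
      Seemingly identical to 'Sol' apart from the lack of m/z 1460.5.

  - name: Gov
    required:
      - {mz: 1329.4, os: os3230, dominant: true}
      - {mz: 1197.4, os: os3220}
      - {mz: 1491.5, os: os4230}
    supporting:
      - {mz: 1343.46, os: os3231}
      - {mz: 1211.4, os: os3221}
    forbidden:
      - {mz: 1460.5, os: os5300}
    oligomannose_methylation: low
    ladders:
      - {base: os3220, direction: up, steps: 2}
    notes: >
      'Jar' subtype with pronounced oligomannose O-methylation, up to
      three methyl groups per glycan.

  - name: Ama
    required:
      - {mz: 1329.4, os: os3230, dominant: true}
      - {mz: 1197.4, os: os3220}
      - {mz: 1491.5, os: os4230}
    supporting:
      - {mz: 1343.46, os: os3231}
      - {mz: 1211.4, os: os3221}
    forbidden:
      - {mz: 1460.5, os: os5300}
    oligomannose_methylation: high
    ladders:
      - {base: os3220, direction: up, steps: 2}
    notes: >
      'Jar' subtype with extreme oligomannose methylation, up to seven
      methyl groups per glycan.

  - name: Asp
    required:
      - {mz: 2079.7, os: os9213, dominant: true}
      - {mz: 2241.8, os: "os[10]213"}
    supporting:
      - {mz: 1329.4, os: os3230}
      - {mz: 1343.46, os: os3231}
      - {mz: 1491.5, os: os4230}
    forbidden: []
    oligomannose_methylation: null
    ladders: []
    notes: >
      Large methylated glycans os9213/os[10]213 on top of a 'Jar'-like
      series.  The series also lists a printed 2565.7 (os[12]213) whose
      arithmetic gives 2565.9; that mass is deliberately excluded from the
      diagnostics (extensible entry).

  - name: Pit
    required:
      - {mz: 1241.4, os: os4211, dominant: true}
      - {mz: 1255.4, os: os4212, dominant: true}
    supporting: []
    forbidden: []
    oligomannose_methylation: null
    ladders: []
    notes: >
      Small xylose-containing glycans os4211/os4212 with methylated
      mannose, no galactose, unsubstituted chitobiose.
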