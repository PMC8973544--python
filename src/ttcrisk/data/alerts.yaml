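# Cohort-of-concern structural alert catalogue.
#
# Each alert fires when any of its SMARTS patterns matches; an alert with
# min_halogens additionally requires at least that many halogen atoms
# (F, Cl, Br, I) anywhere in the molecule.  Entries are matched in file
# order.  Patterns are deliberately minimal: they flag the named class
# for manual review rather than attempt exhaustive QSAR coverage, and
# stricter patterns can be swapped in by editing this file.
alerts:
  - alert_id: n_nitroso
    description: >
      N-nitroso group: a trivalent nitrogen bonded to a nitrogen
      double-bonded to oxygen (nitrosamines, nitrosoureas).
    smarts:
      - "[NX3][NX2]=[OX1]"
  - alert_id: azoxy
    description: >
      Azoxy group: carbon-substituted N=N(+)-O(-), charged form plus the
      uncharged valence-tautomer spelling.
    smarts:
      - "[#6][NX2]=[NX3+][OX1-]"
      - "[#6][NX2]=[NX2]=[OX1]"
  - alert_id: aflatoxin_like
    description: >
      Aflatoxin-like core: the fused furo[2,3-b]furan bicycle (acetal
      carbon shared by two oxygen-bearing five-membered rings), a proxy
      for the aflatoxin bisfuran.
    smarts:
      - "[#6]1~[#6]~[#6]2~[#6](~[#8]~1)~[#8]~[#6]~[#6]~2"
  - alert_id: polyhalogenated_scaffold
    description: >
      Bioaccumulative polyhalogenated scaffold: dibenzo-p-dioxin,
      dibenzofuran or biphenyl core carrying at least four halogens.
    smarts:
      - "c1ccc2Oc3ccccc3Oc2c1"
      - "c1ccc2c(c1)oc1ccccc12"
      - "c1ccc(-c2ccccc2)cc1"
    min_halogens: 4
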