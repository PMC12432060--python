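# Curated diagnostic product-ion library for the phenolic aglycones observed
# in negative-mode stepped-NCE MS2 spectra of seaweed extracts.  m/z values
# are aglycone-level fragments (sulfate diagnostic ions SO3-/HSO4- and
# sulfate-bearing precursor ions are handled separately by the rule engine).
# aromatic_oh / aliphatic_oh describe the free hydroxyls of the aglycone and
# are used to sanity-check sulfation-site calls.  Several entries are
# deliberately isobaric (e.g. phenyllactic vs phloretic acid, C9H10O3) and
# are discriminated by their fragments, mirroring how isomeric suspects are
# told apart in practice.
rules:
  - aglycone: phloroglucinol
    formula: C6H6O3
    subclass: phenol
    aromatic_oh: 3
    aliphatic_oh: 0
    min_required: 1
    diagnostics:
      - {label: "[M-H]-", mz: 125.0243}
  - aglycone: catechol
    formula: C6H6O2
    subclass: phenol
    aromatic_oh: 2
    aliphatic_oh: 0
    min_required: 1
    diagnostics:
      - {label: "[M-H]-", mz: 109.0289}
  - aglycone: phenol
    formula: C6H6O
    subclass: phenol
    aromatic_oh: 1
    aliphatic_oh: 0
    min_required: 1
    diagnostics:
      - {label: "[M-H]-", mz: 93.0340}
  - aglycone: diphloroethol
    formula: C12H10O6
    subclass: phlorotannin
    aromatic_oh: 5
    aliphatic_oh: 0
    min_required: 2
    diagnostics:
      - {label: "[M-H]-", mz: 249.0403}
      - {label: "ring fragment", mz: 141.0193}
      - {label: "ring fragment radical", mz: 140.0114}
      - {label: "phloroglucinol [M-H]-", mz: 125.0243}
  - aglycone: triphloroethol
    formula: C18H14O9
    subclass: phlorotannin
    aromatic_oh: 7
    aliphatic_oh: 0
    min_required: 2
    diagnostics:
      - {label: "[M-H]-", mz: 373.0574}
      - {label: "-C6H6O3", mz: 247.0244}
      - {label: "-C6H6O3 -H2O", mz: 229.0138}
      - {label: "-C6H6O3 -H2O -CO", mz: 201.0190}
      - {label: "phloroglucinol [M-H]-", mz: 125.0242}
  - aglycone: hydroxymethoxybenzoic acid
    formula: C8H8O4
    subclass: phenolic_acid
    aromatic_oh: 1
    aliphatic_oh: 0
    min_required: 2
    diagnostics:
      - {label: "-CO2", mz: 123.0290}
      - {label: "-CO2 -CH3", mz: 108.0211}
  - aglycone: dihydroxyphenyllactic acid
    formula: C9H10O5
    subclass: phenolic_acid
    aromatic_oh: 2
    aliphatic_oh: 1
    min_required: 2
    diagnostics:
      - {label: "[M-H]-", mz: 197.0449}
      - {label: "-H2O", mz: 179.0340}
      - {label: "-H2O -CO2", mz: 135.0445}
      - {label: "ring fragment", mz: 123.0447}
      - {label: "glycolate fragment", mz: 72.9922}
  - aglycone: dihydroxybenzoic acid
    formula: C7H6O4
    subclass: phenolic_acid
    aromatic_oh: 2
    aliphatic_oh: 0
    min_required: 2
    diagnostics:
      - {label: "[M-H]-", mz: 153.0188}
      - {label: "-CO2", mz: 109.0291}
  - aglycone: hydroxybenzaldehyde
    formula: C7H6O2
    subclass: phenol
    aromatic_oh: 1
    aliphatic_oh: 0
    min_required: 1
    diagnostics:
      - {label: "[M-H]-", mz: 121.0289}
      - {label: "-CO", mz: 93.0343}
  - aglycone: dihydroxybenzaldehyde
    formula: C7H6O3
    subclass: phenol
    aromatic_oh: 2
    aliphatic_oh: 0
    min_required: 2
    diagnostics:
      - {label: "[M-H]-", mz: 137.0237}
      - {label: "-CO", mz: 109.0291}
      - {label: "-CO -H radical", mz: 108.0211}
  - aglycone: hydroxybenzoic acid
    formula: C7H6O3
    subclass: phenolic_acid
    aromatic_oh: 1
    aliphatic_oh: 0
    min_required: 2
    diagnostics:
      - {label: "[M-H]-", mz: 137.0238}
      - {label: "-CO2", mz: 93.0339}
  - aglycone: hydroxyphenyllactic acid
    formula: C9H10O4
    subclass: phenolic_acid
    aromatic_oh: 1
    aliphatic_oh: 1
    min_required: 2
    diagnostics:
      - {label: "[M-H]-", mz: 181.0505}
      - {label: "-H2O", mz: 163.0399}
      - {label: "-H2O -CO", mz: 135.0451}
      - {label: "-H2O -CO2", mz: 119.0501}
      - {label: "lactate chain", mz: 101.0241}
      - {label: "lactate chain -H2O", mz: 89.0240}
  - aglycone: hydroxytyrosol
    formula: C8H10O3
    subclass: phenol
    aromatic_oh: 2
    aliphatic_oh: 1
    min_required: 2
    diagnostics:
      - {label: "[M-H]-", mz: 153.0553}
      - {label: "-CH2O", mz: 123.0449}
  - aglycone: tyrosol
    formula: C8H10O2
    subclass: phenol
    aromatic_oh: 1
    aliphatic_oh: 1
    min_required: 1
    diagnostics:
      - {label: "[M-H]-", mz: 137.0607}
  - aglycone: dihydroxyphenylacetic acid
    formula: C8H8O4
    subclass: phenolic_acid
    aromatic_oh: 2
    aliphatic_oh: 0
    min_required: 2
    diagnostics:
      - {label: "[M-H]-", mz: 167.0342}
      - {label: "-CO2", mz: 123.0446}
  - aglycone: hydroxyphenylacetic acid
    formula: C8H8O3
    subclass: phenolic_acid
    aromatic_oh: 1
    aliphatic_oh: 0
    min_required: 2
    diagnostics:
      - {label: "[M-H]-", mz: 151.0396}
      - {label: "-CO2", mz: 107.0499}
  - aglycone: hydroxymethoxyphenylacetic acid
    formula: C9H10O4
    subclass: phenolic_acid
    aromatic_oh: 1
    aliphatic_oh: 0
    min_required: 2
    diagnostics:
      - {label: "[M-H]-", mz: 181.0505}
      - {label: "-CO2 -CH3", mz: 122.0267}
  - aglycone: caffeic acid
    formula: C9H8O4
    subclass: phenolic_acid
    aromatic_oh: 2
    aliphatic_oh: 0
    min_required: 2
    diagnostics:
      - {label: "[M-H]-", mz: 179.0345}
      - {label: "-CO2", mz: 135.0448}
      - {label: "catechol fragment", mz: 109.0291}
  - aglycone: coumaric acid
    formula: C9H8O3
    subclass: phenolic_acid
    aromatic_oh: 1
    aliphatic_oh: 0
    min_required: 2
    diagnostics:
      - {label: "[M-H]-", mz: 163.0391}
      - {label: "-CO2", mz: 119.0496}
  - aglycone: phenyllactic acid
    formula: C9H10O3
    subclass: phenolic_acid
    aromatic_oh: 0
    aliphatic_oh: 1
    min_required: 2
    diagnostics:
      - {label: "[M-H]-", mz: 165.0555}
      - {label: "-H2O", mz: 147.0451}
      - {label: "-H2O -CO", mz: 119.0501}
      - {label: "glycolate fragment", mz: 72.9926}
  - aglycone: phloretic acid
    formula: C9H10O3
    subclass: phenolic_acid
    aromatic_oh: 1
    aliphatic_oh: 0
    min_required: 2
    diagnostics:
      - {label: "[M-H]-", mz: 165.0548}
      - {label: "-CO2", mz: 121.0658}
      - {label: "ring fragment", mz: 95.0495}
      - {label: "phenolate", mz: 93.0342}
  - aglycone: dihydroxycoumarin
    formula: C9H6O4
    subclass: coumarin
    aromatic_oh: 2
    aliphatic_oh: 0
    min_required: 2
    diagnostics:
      - {label: "[M-H]-", mz: 177.0184}
      - {label: "-CO2", mz: 133.0292}
  - aglycone: dihydroxymethylcoumarin
    formula: C10H8O4
    subclass: coumarin
    aromatic_oh: 2
    aliphatic_oh: 0
    min_required: 2
    diagnostics:
      - {label: "[M-H]-", mz: 191.0341}
      - {label: "-CO2", mz: 147.0444}
      - {label: "phenolate", mz: 93.0338}
  - aglycone: dihydroxydimethylcoumarin
    formula: C11H10O4
    subclass: coumarin
    aromatic_oh: 2
    aliphatic_oh: 0
    min_required: 2
    diagnostics:
      - {label: "[M-H]-", mz: 205.0501}
      - {label: "-CO2", mz: 161.0602}
      - {label: "-CO2 -CO", mz: 133.0656}
      - {label: "phenolate", mz: 93.0340}
      - {label: "small ring fragment", mz: 75.0080}
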