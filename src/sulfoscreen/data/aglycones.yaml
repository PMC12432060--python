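# Default aglycone registry: the 32 phenolic scaffolds screened for in
# seaweed extracts, grouped by subclass.  aromatic_oh / aliphatic_oh count
# the free hydroxyl groups available for sulfation (carboxyl OH excluded);
# they are metadata used to sanity-check MS2 sulfation-site calls.
aglycones:
  # -- phenols (6) ----------------------------------------------------------
  - {name: phenol,             formula: C6H6O,    subclass: phenol, aromatic_oh: 1, aliphatic_oh: 0}
  - {name: catechol,           formula: C6H6O2,   subclass: phenol, aromatic_oh: 2, aliphatic_oh: 0}
  - {name: phloroglucinol,     formula: C6H6O3,   subclass: phenol, aromatic_oh: 3, aliphatic_oh: 0}
  - {name: vanillin,           formula: C8H8O3,   subclass: phenol, aromatic_oh: 1, aliphatic_oh: 0}
  - {name: tyrosol,            formula: C8H10O2,  subclass: phenol, aromatic_oh: 1, aliphatic_oh: 1}
  - {name: hydroxytyrosol,     formula: C8H10O3,  subclass: phenol, aromatic_oh: 2, aliphatic_oh: 1}
  # -- phenolic acids (16) --------------------------------------------------
  - {name: benzoic acid,              formula: C7H6O2,   subclass: phenolic_acid, aromatic_oh: 0, aliphatic_oh: 0}
  - {name: hydroxybenzoic acid,       formula: C7H6O3,   subclass: phenolic_acid, aromatic_oh: 1, aliphatic_oh: 0}
  - {name: dihydroxybenzoic acid,     formula: C7H6O4,   subclass: phenolic_acid, aromatic_oh: 2, aliphatic_oh: 0}
  - {name: gallic acid,               formula: C7H6O5,   subclass: phenolic_acid, aromatic_oh: 3, aliphatic_oh: 0}
  - {name: vanillic acid,             formula: C8H8O4,   subclass: phenolic_acid, aromatic_oh: 1, aliphatic_oh: 0}
  - {name: coumaric acid,             formula: C9H8O3,   subclass: phenolic_acid, aromatic_oh: 1, aliphatic_oh: 0}
  - {name: caffeic acid,              formula: C9H8O4,   subclass: phenolic_acid, aromatic_oh: 2, aliphatic_oh: 0}
  - {name: phenyllactic acid,         formula: C9H10O3,  subclass: phenolic_acid, aromatic_oh: 0, aliphatic_oh: 1}
  - {name: hydroxyphenyllactic acid,  formula: C9H10O4,  subclass: phenolic_acid, aromatic_oh: 1, aliphatic_oh: 1}
  - {name: syringic acid,             formula: C9H10O5,  subclass: phenolic_acid, aromatic_oh: 1, aliphatic_oh: 0}
  - {name: ferulic acid,              formula: C10H10O4, subclass: phenolic_acid, aromatic_oh: 1, aliphatic_oh: 0}
  - {name: hydroxyferulic acid,       formula: C10H10O5, subclass: phenolic_acid, aromatic_oh: 2, aliphatic_oh: 0}
  - {name: sinapic acid,              formula: C11H12O5, subclass: phenolic_acid, aromatic_oh: 1, aliphatic_oh: 0}
  - {name: hydroxynaphtoic acid,      formula: C11H8O3,  subclass: phenolic_acid, aromatic_oh: 1, aliphatic_oh: 0}
  - {name: dihydroxynaphtoic acid,    formula: C11H8O4,  subclass: phenolic_acid, aromatic_oh: 2, aliphatic_oh: 0}
  - {name: ellagic acid,              formula: C14H6O8,  subclass: phenolic_acid, aromatic_oh: 4, aliphatic_oh: 0}
  # -- coumarins (4) --------------------------------------------------------
  - {name: hydroxycoumarin,    formula: C9H6O3,   subclass: coumarin, aromatic_oh: 1, aliphatic_oh: 0}
  - {name: dihydroxycoumarin,  formula: C9H6O4,   subclass: coumarin, aromatic_oh: 2, aliphatic_oh: 0}
  - {name: scopoletin,         formula: C10H8O4,  subclass: coumarin, aromatic_oh: 1, aliphatic_oh: 0}
  - {name: scoparone,          formula: C11H10O4, subclass: coumarin, aromatic_oh: 0, aliphatic_oh: 0}
  # -- phlorotannins (6) ----------------------------------------------------
  # phloroethol oligomers follow a -H2-per-aryl-ether-coupling pattern from
  # phloroglucinol units; eckol dimer is the dieckol-type C-C coupled dimer
  # (2 x eckol - H2).
  - {name: diphloroethol,      formula: C12H10O6,  subclass: phlorotannin, aromatic_oh: 5,  aliphatic_oh: 0}
  - {name: triphloroethol,     formula: C18H14O9,  subclass: phlorotannin, aromatic_oh: 7,  aliphatic_oh: 0}
  - {name: tetraphloroethol,   formula: C24H18O12, subclass: phlorotannin, aromatic_oh: 9,  aliphatic_oh: 0}
  - {name: eckol,              formula: C18H12O9,  subclass: phlorotannin, aromatic_oh: 6,  aliphatic_oh: 0}
  - {name: eckol dimer,        formula: C36H22O18, subclass: phlorotannin, aromatic_oh: 11, aliphatic_oh: 0}
  - {name: bifuhalol,          formula: C12H10O7,  subclass: phlorotannin, aromatic_oh: 6,  aliphatic_oh: 0}

# Sugar / sugar-like conjugate moieties; delta_formula is the composition
# added on condensation (free moiety minus H2O).
moieties:
  - {name: hexose,        delta_formula: C6H10O5}
  - {name: pentose,       delta_formula: C5H8O4}
  - {name: quinic acid,   delta_formula: C7H10O5}
  - {name: shikimic acid, delta_formula: C7H8O4}
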