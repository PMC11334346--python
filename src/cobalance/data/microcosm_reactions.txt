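# Redox reaction ledger of a CO-fed TCE-dechlorinating microcosm.
# One reaction per line: "name: lhs -> rhs ; dG=<kJ/mol>" (standard state:
# 298.15 K, gases 1 atm, solutes 1 M; dG is the ledger constant).
tce_dechlorination: TCE + 3 H2(g) -> ethene(g) + 3 HCl ; dG=-150.5
h2_formation: CO(g) + H2O(l) -> CO2(g) + H2(g) ; dG=-20.1
acetogenesis_h2: 2 CO2(g) + 4 H2(g) -> 2 H2O(l) + CH3COOH ; dG=-75.3
acetogenesis_co: 4 CO(g) + 2 H2O(l) -> 2 CO2(g) + CH3COOH ; dG=-155.7
methanogenesis_acetate: CH3COOH -> CO2(g) + CH4(g) ; dG=-55.0
methanogenesis_h2: CO2(g) + 4 H2(g) -> 2 H2O(l) + CH4(g) ; dG=-130.3
methanogenesis_co: 4 CO(g) + 2 H2O(l) -> 3 CO2(g) + CH4(g) ; dG=-210.7
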