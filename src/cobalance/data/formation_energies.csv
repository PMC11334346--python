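name,formula,phase,dfG_kJ_per_mol,source
H2,H2,gas,0.0,reference state
CO,CO,gas,-137.2,CRC Handbook 84th ed.
CO2,CO2,gas,-394.4,CRC Handbook 84th ed.
H2O,H2O,liquid,-237.1,CRC Handbook 84th ed.
CH4,CH4,gas,-50.5,CRC Handbook 84th ed.
ethene,C2H4,gas,68.4,CRC Handbook 84th ed.
acetate,C2H4O2,liquid,-389.9,CRC Handbook 84th ed. (acetic acid l)
HCl,HCl,gas,-95.3,CRC Handbook 84th ed.
TCE,C2HCl3,aqueous,,
cDCE,C2H2Cl2,aqueous,,
VC,C2H3Cl,aqueous,,
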