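treatment,role,species,umol
2 mL/dose CO,substrate,CO,571.4
2 mL/dose CO,substrate,TCE,38.2
2 mL/dose CO,product,CH4,3.2
2 mL/dose CO,product,ethene,28.7
2 mL/dose CO,product,acetate,170.1
5 mL/dose CO,substrate,CO,1428.6
5 mL/dose CO,substrate,TCE,35.8
5 mL/dose CO,product,CH4,11.0
5 mL/dose CO,product,ethene,25.5
5 mL/dose CO,product,acetate,349.6
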