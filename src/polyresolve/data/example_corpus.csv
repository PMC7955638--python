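standard_name,usmiles,density,abbreviations,synonyms,trade_names
Polystyrene,*CC(*)c1ccccc1,1.04,PS,,Styrofoam
Poly(vinyl alcohol),,,PVA,,
Poly(vinyl acetate),,,PVA,,
Diglycidyl ether of bisphenol-A,,,DGEBA,Diglycidyl ether of bisphenol-A epoxy resin,
Nylon 66,,,PA 66,Polyamide 66,
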