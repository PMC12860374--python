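name,formula,classes
Hexosyl,C6H10O5,flavonol;phenolic acid;lignan;resin glycoside;oligosaccharide
Rhamnosyl,C6H10O4,flavonol;resin glycoside;oligosaccharide
Pentosyl,C5H8O4,flavonol;resin glycoside;oligosaccharide
Caffeoyl,C9H6O3,flavonol;phenolic acid
Feruloyl,C10H8O3,flavonol;phenolic acid
Coumaroyl,C9H6O2,flavonol;phenolic acid
Acetyl,C2H2O,flavonol;resin glycoside
Methyl,CH2,flavonol;phenolic acid;alkaloid
Formyl,CO,alkaloid
Hydroxyhexadecanoyl,C16H30O2,resin glycoside
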