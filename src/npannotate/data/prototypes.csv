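name,formula,class,source,standard
p-Coumaric acid,C9H8O3,phenolic acid,representative absorbed compound,1
Caffeic acid,C9H8O4,phenolic acid,representative absorbed compound,1
Ferulic acid,C10H10O4,phenolic acid,representative absorbed compound,1
Hyperoside,C21H20O12,flavonol,representative absorbed compound,1
Isorhamnetin-7-O-glucoside,C22H22O12,flavonol,representative absorbed compound,1
Kaempferol,C15H10O6,flavonol,representative absorbed compound,1
Quercetin,C15H10O7,flavonol,representative absorbed compound,1
Isorhamnetin,C16H12O7,flavonol,representative absorbed compound,1
Cuscutamine,C15H14N2O3,alkaloid,representative absorbed compound,1
Sesaminol,C20H18O7,lignan,representative absorbed compound,0
Sesamin,C20H18O6,lignan,representative absorbed compound,0
Pinoresinol,C20H22O6,lignan,representative absorbed compound,0
Piperitol,C20H20O6,lignan,representative absorbed compound,0
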