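name,formula,class,source,standard
Raffinose,C18H32O16,oligosaccharide,reported constituent,1
Sucrose,C12H22O11,oligosaccharide,reported constituent,1
Neochlorogenic acid,C16H18O9,phenolic acid,reported constituent,1
Chlorogenic acid,C16H18O9,phenolic acid,reported constituent,1
Cryptochlorogenic acid,C16H18O9,phenolic acid,reported constituent,1
Caffeic acid,C9H8O4,phenolic acid,reported constituent,1
p-Coumaric acid,C9H8O3,phenolic acid,reported constituent,1
Quinic acid,C7H12O6,phenolic acid,reported constituent,0
p-Coumaroylquinic acid,C16H18O8,phenolic acid,reported constituent,0
Feruloylquinic acid,C17H20O9,phenolic acid,reported constituent,0
Isochlorogenic acid C,C25H24O12,phenolic acid,reported constituent,1
Ferulic acid,C10H10O4,phenolic acid,reported constituent,1
Hyperoside,C21H20O12,flavonol,reported constituent,1
Isoquercitrin,C21H20O12,flavonol,reported constituent,1
Astragalin,C21H20O11,flavonol,reported constituent,1
Isorhamnetin-3-O-glucoside,C22H22O12,flavonol,reported constituent,1
Isorhamnetin-7-O-glucoside,C22H22O12,flavonol,reported constituent,1
Kaempferol,C15H10O6,flavonol,reported constituent,1
Quercetin,C15H10O7,flavonol,reported constituent,1
Isorhamnetin,C16H12O7,flavonol,reported constituent,1
Cuscutamine,C15H14N2O3,alkaloid,reported constituent,1
Sesaminol diglucoside,C32H38O17,lignan,reported constituent,1
Sesaminol,C20H18O7,lignan,reported constituent,0
LPC 16:0,C24H50NO7P,phospholipid,reported constituent,1
LPC 18:2,C26H50NO7P,phospholipid,reported constituent,0
Cus 1,C39H68O19,resin glycoside,reported constituent,0
Cus 3,C37H66O18,resin glycoside,reported constituent,0
Azelaic acid,C9H16O4,fatty acid,reported constituent,1
Hydroxytetradecanoic acid,C14H28O3,fatty acid,reported constituent,0
Dihydroxyhexadecanoic acid,C16H32O4,fatty acid,reported constituent,0
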