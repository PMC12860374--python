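name,kind,polarity,formula,exact_mass,class
# phenolic acid diagnostic ions (negative mode)
Caffeic acid anion,diagnostic,negative,C9H8O4,179.0344,phenolic acid
Cinnamic acid anion,diagnostic,negative,C9H8O2,147.0446,phenolic acid
Coumaric acid anion,diagnostic,negative,C9H8O3,163.0395,phenolic acid
Quinic acid anion,diagnostic,negative,C7H12O6,191.0556,phenolic acid
Quinic acid-H2O anion,diagnostic,negative,C7H10O5,173.0450,phenolic acid
Ferulic acid anion,diagnostic,negative,C10H10O4,193.0501,phenolic acid
Coumaroylquinic acid anion,diagnostic,negative,C16H18O8,337.0923,phenolic acid
Caffeoylquinic acid anion,diagnostic,negative,C16H18O9,353.0873,phenolic acid
Feruloylquinic acid anion,diagnostic,negative,C17H20O9,367.1029,phenolic acid
# phenolic acid diagnostic ions (positive mode)
Caffeic acid cation,diagnostic,positive,C9H8O4,181.0501,phenolic acid
Coumaric acid cation,diagnostic,positive,C9H8O3,165.0552,phenolic acid
Ferulic acid cation,diagnostic,positive,C10H10O4,195.0657,phenolic acid
Caffeoylquinic acid cation,diagnostic,positive,C16H18O9,355.1029,phenolic acid
# phenolic acid neutral losses
Feruloyl loss,neutral_loss,both,C10H8O3,176.0473,phenolic acid
Coumaroyl loss,neutral_loss,both,C9H6O2,146.0368,phenolic acid
Cinnamoyl loss,neutral_loss,both,C9H6O,130.0419,phenolic acid
Caffeoyl loss,neutral_loss,both,C9H6O3,162.0317,phenolic acid
Quinic acid loss,neutral_loss,both,C7H12O6,192.0634,phenolic acid
Hexosyl loss,neutral_loss,both,C6H10O5,162.0528,phenolic acid
Sucrose residue loss,neutral_loss,both,C12H20O10,324.1057,phenolic acid
Raffinose residue loss,neutral_loss,both,C18H30O15,486.1585,phenolic acid
Stachyose residue loss,neutral_loss,both,C24H40O20,648.2113,phenolic acid
# flavonol diagnostic ions
Kaempferol anion,diagnostic,negative,C15H10O6,285.0399,flavonol
Quercetin anion,diagnostic,negative,C15H10O7,301.0348,flavonol
Isorhamnetin anion,diagnostic,negative,C16H12O7,315.0505,flavonol
Flavonol RDA fragment anion,diagnostic,negative,C7H4O4,151.0031,flavonol
Kaempferol cation,diagnostic,positive,C15H10O6,287.0556,flavonol
Quercetin cation,diagnostic,positive,C15H10O7,303.0505,flavonol
Isorhamnetin cation,diagnostic,positive,C16H12O7,317.0661,flavonol
Flavonol RDA fragment cation,diagnostic,positive,C7H4O4,153.0188,flavonol
# flavonol neutral losses
Hexosyl loss,neutral_loss,both,C6H10O5,162.0528,flavonol
Rhamnosyl loss,neutral_loss,both,C6H10O4,146.0579,flavonol
Pentosyl loss,neutral_loss,both,C5H8O4,132.0423,flavonol
Caffeoyl loss,neutral_loss,both,C9H6O3,162.0317,flavonol
Coumaroyl loss,neutral_loss,both,C9H6O2,146.0368,flavonol
Feruloyl loss,neutral_loss,both,C10H8O3,176.0473,flavonol
Glucuronosyl loss,neutral_loss,both,C6H8O6,176.0321,flavonol
Sulfo loss,neutral_loss,both,SO3,79.9568,flavonol
Glucuronosyl loss,neutral_loss,both,C6H8O6,176.0321,phenolic acid
Sulfo loss,neutral_loss,both,SO3,79.9568,phenolic acid
# resin glycoside diagnostic ions (negative mode)
Rhamnose-acetylglucosyl anion,diagnostic,negative,,351.1291,resin glycoside
Hydroxyhexadecanoic acid anion,diagnostic,negative,C16H32O3,271.2273,resin glycoside
Hydroxytetradecanoic acid anion,diagnostic,negative,C14H28O3,243.1960,resin glycoside
Hydroxymethylbutanoic acid anion,diagnostic,negative,,117.0557,resin glycoside
# resin glycoside neutral losses
Acetylhexosyl loss,neutral_loss,both,C8H12O6,204.0634,resin glycoside
Hexosyl loss,neutral_loss,both,C6H10O5,162.0528,resin glycoside
Rhamnosyl loss,neutral_loss,both,C6H10O4,146.0579,resin glycoside
# phospholipid diagnostic ions (positive mode)
Phosphocholine cation,diagnostic,positive,C5H14NO4P,184.0739,phospholipid
Phosphocholine-H2O cation,diagnostic,positive,C5H12NO3P,166.0633,phospholipid
Cyclic ethylene phosphate cation,diagnostic,positive,C2H5O4P,125.0004,phospholipid
Choline cation,diagnostic,positive,C5H13NO,104.1075,phospholipid
Trimethylethenaminium cation,diagnostic,positive,C5H11N,86.0970,phospholipid
Linoleoyl glyceryl cation,diagnostic,positive,C21H36O3,337.2743,phospholipid
Palmitoyl glyceryl cation,diagnostic,positive,C19H36O3,313.2743,phospholipid
# phospholipid neutral losses
Fatty acyl loss (linoleoyl),neutral_loss,both,C18H30O,262.2297,phospholipid
Fatty acyl loss (palmitoyl),neutral_loss,both,C16H30O,238.2297,phospholipid
# alkaloid diagnostic ions
Alkaloid core cation (225),diagnostic,positive,C14H12N2O,225.1028,alkaloid
Alkaloid core-CO cation,diagnostic,positive,,197.1073,alkaloid
Alkaloid core-CO-NH3 cation,diagnostic,positive,,180.0813,alkaloid
Alkaloid core-CO-C2H4 cation,diagnostic,positive,,169.0766,alkaloid
Alkaloid core anion (225),diagnostic,negative,C14H14N2O,225.1028,alkaloid
Alkaloid core anion (183),diagnostic,negative,C12H12N2,183.0922,alkaloid
Alkaloid C11H10N anion,diagnostic,negative,,156.0822,alkaloid
# alkaloid neutral losses
Formic acid loss,neutral_loss,both,CH2O2,46.0055,alkaloid
CO loss,neutral_loss,both,CO,27.9949,alkaloid
NH3 loss,neutral_loss,both,NH3,17.0265,alkaloid
C2H4 loss,neutral_loss,both,C2H4,28.0313,alkaloid
CH2 loss,neutral_loss,both,CH2,14.0157,alkaloid
CO2 loss,neutral_loss,both,CO2,43.9898,alkaloid
# lignan signatures
Sesaminol anion,diagnostic,negative,,369.0988,lignan
Hexosyl loss,neutral_loss,both,C6H10O5,162.0528,lignan
Dihexosyl loss,neutral_loss,both,C12H20O10,324.1057,lignan
# oligosaccharide signatures
Hexose anion,diagnostic,negative,C6H12O6,179.0556,oligosaccharide
Dihexose anion,diagnostic,negative,C12H22O11,341.1084,oligosaccharide
Hexosyl loss,neutral_loss,both,C6H10O5,162.0528,oligosaccharide
Pentosyl loss,neutral_loss,both,C5H8O4,132.0423,oligosaccharide
Rhamnosyl loss,neutral_loss,both,C6H10O4,146.0579,oligosaccharide
# generic losses, not class-evidence
Water loss,neutral_loss,both,H2O,18.0106,other
CO2 loss (generic),neutral_loss,both,CO2,43.9898,other
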