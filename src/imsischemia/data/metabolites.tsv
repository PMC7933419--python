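name	formula	pathways
ATP	C10H16N5O13P3	Purine metabolism;Oxidative phosphorylation
ADP	C10H15N5O10P2	Purine metabolism;Oxidative phosphorylation
AMP	C10H14N5O7P	Purine metabolism
IMP	C10H13N4O8P	Purine metabolism
GTP	C10H16N5O14P3	Purine metabolism
GDP	C10H15N5O11P2	Purine metabolism
Hypoxanthine	C5H4N4O	Purine metabolism
Inosine	C10H12N4O5	Purine metabolism
NADH	C21H29N7O14P2	Nicotinate and nicotinamide metabolism;Oxidative phosphorylation
S-NADHX	C21H31N7O15P2	Nicotinate and nicotinamide metabolism
Nicotinamide	C6H6N2O	Nicotinate and nicotinamide metabolism
L-Glutamic acid	C5H9NO4	Alanine, aspartate and glutamate metabolism;Glutathione metabolism
L-Aspartic acid	C4H7NO4	Alanine, aspartate and glutamate metabolism
Glutathione	C10H17N3O6S	Glutathione metabolism
Taurine	C2H7NO3S	Taurine and hypotaurine metabolism
Lactic acid	C3H6O3	Glycolysis
Pyruvic acid	C3H4O3	Glycolysis;Citrate cycle
Glucose 6-phosphate	C6H13O9P	Glycolysis;Pentose phosphate pathway
Fructose 1,6-bisphosphate	C6H14O12P2	Glycolysis
Citric acid	C6H8O7	Citrate cycle
Malic acid	C4H6O5	Citrate cycle
Succinic acid	C4H6O4	Citrate cycle
Fumaric acid	C4H4O4	Citrate cycle
D-Glucuronic acid 1-phosphate	C6H11O10P	Amino sugar and nucleotide sugar metabolism
UDP-glucuronic acid	C15H22N2O18P2	Amino sugar and nucleotide sugar metabolism
UDP-N-acetylglucosamine	C17H27N3O17P2	Amino sugar and nucleotide sugar metabolism
Inositol cyclic phosphate	C6H11O8P	Inositol phosphate metabolism
Glycerol 3-phosphate	C3H9O6P	Glycerophospholipid metabolism
Oleic acid	C18H34O2	Fatty acid biosynthesis
Palmitic acid	C16H32O2	Fatty acid biosynthesis
Stearic acid	C18H36O2	Fatty acid biosynthesis
Creatine phosphate	C4H10N3O5P	Arginine and proline metabolism
Ascorbic acid	C6H8O6	Ascorbate and aldarate metabolism
Phosphoenolpyruvic acid	C3H5O6P	Glycolysis
Glyceraldehyde 3-phosphate	C3H7O6P	Glycolysis
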