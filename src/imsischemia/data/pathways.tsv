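pathway	metabolite
Purine metabolism	ATP
Oxidative phosphorylation	ATP
Purine metabolism	ADP
Oxidative phosphorylation	ADP
Purine metabolism	AMP
Purine metabolism	IMP
Purine metabolism	GTP
Purine metabolism	GDP
Purine metabolism	Hypoxanthine
Purine metabolism	Inosine
Nicotinate and nicotinamide metabolism	NADH
Oxidative phosphorylation	NADH
Nicotinate and nicotinamide metabolism	S-NADHX
Nicotinate and nicotinamide metabolism	Nicotinamide
Alanine, aspartate and glutamate metabolism	L-Glutamic acid
Glutathione metabolism	L-Glutamic acid
Alanine, aspartate and glutamate metabolism	L-Aspartic acid
Glutathione metabolism	Glutathione
Taurine and hypotaurine metabolism	Taurine
Glycolysis	Lactic acid
Glycolysis	Pyruvic acid
Citrate cycle	Pyruvic acid
Glycolysis	Glucose 6-phosphate
Pentose phosphate pathway	Glucose 6-phosphate
Glycolysis	Fructose 1,6-bisphosphate
Citrate cycle	Citric acid
Citrate cycle	Malic acid
Citrate cycle	Succinic acid
Citrate cycle	Fumaric acid
Amino sugar and nucleotide sugar metabolism	D-Glucuronic acid 1-phosphate
Amino sugar and nucleotide sugar metabolism	UDP-glucuronic acid
Amino sugar and nucleotide sugar metabolism	UDP-N-acetylglucosamine
Inositol phosphate metabolism	Inositol cyclic phosphate
Glycerophospholipid metabolism	Glycerol 3-phosphate
Fatty acid biosynthesis	Oleic acid
Fatty acid biosynthesis	Palmitic acid
Fatty acid biosynthesis	Stearic acid
Arginine and proline metabolism	Creatine phosphate
Ascorbate and aldarate metabolism	Ascorbic acid
Glycolysis	Phosphoenolpyruvic acid
Glycolysis	Glyceraldehyde 3-phosphate
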