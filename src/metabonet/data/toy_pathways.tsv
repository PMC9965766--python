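pathway_id	pathway_name	compound	importance
TOY001	Glycolysis / Gluconeogenesis	glucose	0.25
TOY001	Glycolysis / Gluconeogenesis	fructose 1,6-bisphosphate	0.15
TOY001	Glycolysis / Gluconeogenesis	glyceraldehyde 3-phosphate	0.10
TOY001	Glycolysis / Gluconeogenesis	phosphoenolpyruvate	0.20
TOY001	Glycolysis / Gluconeogenesis	pyruvate	0.20
TOY001	Glycolysis / Gluconeogenesis	lactate	0.10
TOY002	Citrate cycle (TCA cycle)	citrate	0.20
TOY002	Citrate cycle (TCA cycle)	aconitate	0.10
TOY002	Citrate cycle (TCA cycle)	succinate	0.20
TOY002	Citrate cycle (TCA cycle)	fumarate	0.15
TOY002	Citrate cycle (TCA cycle)	malate	0.15
TOY002	Citrate cycle (TCA cycle)	oxaloacetate	0.20
TOY003	Phenylalanine, tyrosine and tryptophan biosynthesis	phenylalanine	0.50
TOY003	Phenylalanine, tyrosine and tryptophan biosynthesis	tyrosine	0.30
TOY003	Phenylalanine, tyrosine and tryptophan biosynthesis	tryptophan	0.20
TOY004	Phenylalanine metabolism	phenylalanine	0.40
TOY004	Phenylalanine metabolism	tyrosine	0.25
TOY004	Phenylalanine metabolism	hippuric acid	0.20
TOY004	Phenylalanine metabolism	homogentisate	0.15
TOY005	Synthesis and degradation of ketone bodies	acetoacetate	0.50
TOY005	Synthesis and degradation of ketone bodies	3-hydroxybutyric acid	0.50
TOY006	Glycine, serine and threonine metabolism	glycine	0.30
TOY006	Glycine, serine and threonine metabolism	serine	0.30
TOY006	Glycine, serine and threonine metabolism	threonine	0.15
TOY006	Glycine, serine and threonine metabolism	betaine	0.10
TOY006	Glycine, serine and threonine metabolism	dimethylglycine	0.15
TOY007	Arginine and proline metabolism	arginine	0.30
TOY007	Arginine and proline metabolism	proline	0.25
TOY007	Arginine and proline metabolism	ornithine	0.20
TOY007	Arginine and proline metabolism	guanidinoacetate	0.15
TOY007	Arginine and proline metabolism	creatinine	0.10
TOY008	Tryptophan metabolism	tryptophan	0.40
TOY008	Tryptophan metabolism	kynurenine	0.25
TOY008	Tryptophan metabolism	xanthurenate	0.20
TOY008	Tryptophan metabolism	serotonin	0.15
TOY009	Branched-chain amino acid degradation	leucine	0.35
TOY009	Branched-chain amino acid degradation	isoleucine	0.30
TOY009	Branched-chain amino acid degradation	valine	0.35
TOY010	Purine metabolism	adenosine	0.25
TOY010	Purine metabolism	inosine monophosphate	0.15
TOY010	Purine metabolism	urate	0.25
TOY010	Purine metabolism	allantoin	0.15
TOY010	Purine metabolism	adenylsuccinate	0.20
TOY011	Pyrimidine metabolism	cytidine	0.30
TOY011	Pyrimidine metabolism	uridine	0.30
TOY011	Pyrimidine metabolism	orotate	0.25
TOY011	Pyrimidine metabolism	2-deoxyuridine	0.15
TOY012	Fructose and mannose metabolism	fructose	0.45
TOY012	Fructose and mannose metabolism	mannose	0.35
TOY012	Fructose and mannose metabolism	sorbitol	0.20
TOY013	Bile acid biosynthesis	glycocholate	0.40
TOY013	Bile acid biosynthesis	glycochenodeoxycholate	0.40
TOY013	Bile acid biosynthesis	taurocholate	0.20
TOY014	Fatty acid biosynthesis	linoleic acid	0.35
TOY014	Fatty acid biosynthesis	linolenic acid	0.35
TOY014	Fatty acid biosynthesis	margaric acid	0.30
TOY015	Histidine metabolism	histidine	0.50
TOY015	Histidine metabolism	carnosine	0.25
TOY015	Histidine metabolism	1-methylhistidine	0.25
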