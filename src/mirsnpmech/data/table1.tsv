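#SNP	Gene	Effects	Traits
rs1121	PDXDC1	MRE creation	Height
rs4564	DLD	MRE disruption	Ulcerative Colitis
rs6706	TRIP6	MRE disruption	Resting Heart Rate
rs7089	TMUB2	MRE disruption; MRE creation	Bone Density
rs7097	POLR1D	MRE creation	Large B-Cell Lymphoma
rs7118	ZFP90	MRE disruption; MRE creation	Ulcerative Colitis
rs7119	HMG20A	MRE disruption	Type 2 Diabetes
rs7371	GNAI3	Acceptor gain	Major Depressive Disorder
rs7444	UBE2L3	Folding	Crohn’s Disease; Systemic Lupus Erythematosus
rs8523	ELOVL2	MRE disruption; MRE creation	Phospholipid levels
rs9253	MEAF6	MRE disruption	Hematological Phenotypes
rs9927	PYGB	MRE creation	Liver Enzyme Levels
rs10923	SMC4	MRE disruption; MRE creation	PBC
rs11700	E2F4	MRE creation	Coronary Heart Disease
rs12439	CLIC4	MRE disruption; MRE creation	Height
rs12916	HMGCR	MRE creation	Cholesterol levels; Metabolic Traits
rs12956	RYBP	Folding	Height
rs13099	TMED10	Folding	Height
rs42038	CDK6	Folding; Acceptor gain	Height
rs42039	CDK6	MRE creation	Rheumatoid Arthritis
rs232775	MYSM1	MRE creation	Diabetic Retinopathy
rs699779	NOTCH2	Acceptor gain; MRE disruption	Type 2 Diabetes
rs823136	RAB7L1	MRE creation	Parkinson’s Disease
rs835575	NOTCH2	Folding; MRE disruption; MRE creation	Type 2 Diabetes
rs835576	NOTCH2	MRE disruption; MRE creation	Type 2 Diabetes
rs1045100	ATG16L1	MRE disruption; MRE creation	Crohn’s Disease
rs1045407	ZNF678	Folding; MRE creation	Height
rs1046917	FN3KRP	Folding	Glycated Hemoglobin Levels
rs1047440	CEP120	MRE disruption; MRE creation	Body Mass Index
rs1058588	VAMP8	MRE disruption	Prostate Cancer
rs1379659	SLIT2	MRE disruption	Echocardiographic Traits
rs2032933	RMI2	MRE creation	Celiac Disease
rs2071518	NOV	MRE creation	Blood Pressure
rs2077579	DDX6	Folding	PBC
rs2229302	HOXB2	MRE disruption; MRE creation	Primary Tooth Development
rs2244967	VSTM4	Acceptor gain	Serum Uric Acid
rs2282301	RIT1	Folding	Conduct Disorder
rs2293578	SLC39A13	MRE creation	Body Mass Index
rs2564921	RFT1	Folding	Height
rs3816661	CD276	MRE disruption	Liver Enzyme Levels
rs3821301	TANC1	Folding	Sudden Cardiac Arrest
rs4770433	SACS	MRE disruption	Protein Quantitative Trait Loci
rs4819388	ICOSLG	Folding; MRE creation	Celiac Disease
rs4973768	SLC4A7	Donor gain	Breast Cancer
rs6722332	WDR12	Acceptor gain	Coronary Heart Disease; Myocardial Infarction
rs7350928	KIAA1267	MRE disruption; MRE creation	Parkinson’s Disease
rs7528419	CELSR2	Acceptor gain	Cholesterol levels; Metabolic traits; Cardiovascular Disease; Myocardial Infarction; Response to Statins
rs8176751	ABO	MRE creation	Hematological Phenotypes
rs10892082	PAFAH1B2	Folding	Protein QTLs; Triglyceride Levels
rs11067231	MMAB	MRE creation	Cholesterol levels
rs11542478	FAM110C	Folding	Information Processing Speed
rs11713355	SLC6A6	MRE disruption; MRE creation	Cognitive Performance
rs17574361	KIAA1267	MRE disruption; MRE creation	Parkinson’s Disease
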