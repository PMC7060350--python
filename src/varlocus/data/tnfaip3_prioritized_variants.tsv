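# Curated high-priority variants at the TNFAIP3 locus: SNPs that are hits in
# CRISPRi or in T-MPRA while lying in accessible chromatin, with their
# GWAS traits, UK Biobank 95% credible-set support (SuSiE), and the
# disease-associated haplotype(s) they belong to.  Multiple haplotype ids
# are comma-separated; ukbb_cs_95 is empty when the SNP is in no credible set.
snp_id	traits	ukbb_cs_95	haplotypes	criteria
rs200820567	Allergy;ISD;RA;SLE;eosinophil counts;IgA deficiency;Sjogren's	Eosinophil counts (PIP=0.03);Allergy (PIP=0.04)	2	T-MPRA+accessible
rs148314165	Allergy;ISD;RA;SLE;eosinophil counts;IgA deficiency;Sjogren's		2	T-MPRA+accessible
rs112497003	Allergy;ISD;RA;SLE;eosinophil counts;IgA deficiency;Sjogren's	Eosinophil counts (PIP=0.01)	2	T-MPRA+accessible
rs111883038	Allergy;ISD;RA;SLE;eosinophil counts;IgA deficiency;Sjogren's	Eosinophil counts (PIP=0.01)	2	L-MPRA+accessible;T-MPRA+accessible
rs6927172	Celiac;IBD;RA;Asthma;IgA deficiency;Sjogren's;ISD;T1D;primary biliary cirrhosis	Combined Autoimmune (PIP=0.13)	6	T-MPRA+accessible
rs643177	ISD;psoriasis		9	L-MPRA+accessible;T-MPRA+accessible
rs59086769	Urine metabolites		5	T-MPRA+accessible
rs1002658	Celiac		14	T-MPRA+accessible
rs11758213	MS		15	T-MPRA+accessible
rs9389527	MS		15	T-MPRA+accessible
rs12201430	Blood metabolites		4	T-MPRA+accessible
rs12192746	Blood metabolites		4	L-MPRA+accessible;T-MPRA+accessible
rs34654849	MS;IgA deficiency;RA		1	T-MPRA+accessible
rs73558137	MS;IgA deficiency;RA		1	T-MPRA+accessible
rs5029924	Allergy;ISD;RA;SLE;eosinophil counts;IgA deficiency;Sjogren's		2	CRISPRi
rs5029926	Allergy;ISD;RA;SLE;eosinophil counts;IgA deficiency;Sjogren's		2,3	CRISPRi
rs10499197	Allergy;ISD;RA;SLE;eosinophil counts;IgA deficiency;Sjogren's		2	T-MPRA+accessible;CRISPRi
rs58905141	Allergy;ISD;RA;SLE;eosinophil counts;IgA deficiency;Sjogren's	Eosinophil counts (PIP=0.02)	2	L-MPRA+accessible;CRISPRi
rs559766217	ISD;Psoriasis		9	CRISPRi
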