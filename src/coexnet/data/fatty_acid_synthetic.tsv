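gene_id	subpathway
SYNFATG001	M00082_fa_initiation
SYNFATG002	M00082_fa_initiation
SYNFATG003	M00082_fa_initiation
SYNFATG004	M00082_fa_initiation
SYNFATG005	M00082_fa_initiation
SYNFATG006	M00082_fa_initiation
SYNFATG007	M00082_fa_initiation
SYNFATG008	M00082_fa_initiation
SYNFATG009	M00082_fa_initiation
SYNFATG010	M00082_fa_initiation
SYNFATG011	M00082_fa_initiation
SYNFATG012	M00082_fa_initiation
SYNFATG013	M00082_fa_initiation
SYNFATG014	M00082_fa_initiation
SYNFATG015	M00082_fa_initiation
SYNFATG016	M00082_fa_initiation
SYNFATG017	M00082_fa_initiation
SYNFATG018	M00082_fa_initiation
SYNFATG019	M00082_fa_initiation
SYNFATG020	M00082_fa_initiation
SYNFATG021	M00082_fa_initiation
SYNFATG022	M00082_fa_initiation
SYNFATG023	M00082_fa_initiation
SYNFATG024	M00082_fa_initiation
SYNFATG025	M00083_fa_elongation
SYNFATG026	M00083_fa_elongation
SYNFATG027	M00083_fa_elongation
SYNFATG028	M00083_fa_elongation
SYNFATG029	M00083_fa_elongation
SYNFATG030	M00083_fa_elongation
SYNFATG031	M00083_fa_elongation
SYNFATG032	M00083_fa_elongation
SYNFATG033	M00083_fa_elongation
SYNFATG034	M00083_fa_elongation
SYNFATG035	M00083_fa_elongation
SYNFATG036	M00083_fa_elongation
SYNFATG037	M00083_fa_elongation
SYNFATG038	M00083_fa_elongation
SYNFATG039	M00083_fa_elongation
SYNFATG040	M00083_fa_elongation
SYNFATG041	M00083_fa_elongation
SYNFATG042	M00083_fa_elongation
SYNFATG043	M00415_fa_elongation_er
SYNFATG044	M00415_fa_elongation_er
SYNFATG045	M00415_fa_elongation_er
SYNFATG046	M00415_fa_elongation_er
SYNFATG047	M00415_fa_elongation_er
SYNFATG048	M00415_fa_elongation_er
SYNFATG049	M00415_fa_elongation_er
SYNFATG050	M00415_fa_elongation_er
SYNFATG051	M00415_fa_elongation_er
SYNFATG052	M00415_fa_elongation_er
SYNFATG053	M00415_fa_elongation_er
SYNFATG054	M00415_fa_elongation_er
SYNFATG055	M00415_fa_elongation_er
SYNFATG056	M00113_jasmonate
SYNFATG057	M00113_jasmonate
SYNFATG058	M00113_jasmonate
SYNFATG059	M00113_jasmonate
SYNFATG060	M00113_jasmonate
SYNFATG061	M00113_jasmonate
SYNFATG062	M00113_jasmonate
SYNFATG063	M00113_jasmonate
SYNFATG064	M00113_jasmonate
SYNFATG065	M00113_jasmonate
SYNFATG066	M00113_jasmonate
SYNFATG067	M00113_jasmonate
SYNFATG068	M00113_jasmonate
SYNFATG069	M00113_jasmonate
SYNFATG070	M00113_jasmonate
SYNFATG071	M00113_jasmonate
SYNFATG072	M00086_beta_oxidation_acylcoa
SYNFATG073	M00086_beta_oxidation_acylcoa
SYNFATG074	M00086_beta_oxidation_acylcoa
SYNFATG075	M00086_beta_oxidation_acylcoa
SYNFATG076	M00086_beta_oxidation_acylcoa
SYNFATG077	M00086_beta_oxidation_acylcoa
SYNFATG078	M00086_beta_oxidation_acylcoa
SYNFATG079	M00086_beta_oxidation_acylcoa
SYNFATG080	M00086_beta_oxidation_acylcoa
SYNFATG081	M00086_beta_oxidation_acylcoa
SYNFATG082	M00086_beta_oxidation_acylcoa
SYNFATG083	M00086_beta_oxidation_acylcoa
SYNFATG084	M00087_beta_oxidation
SYNFATG085	M00087_beta_oxidation
SYNFATG086	M00087_beta_oxidation
SYNFATG087	M00087_beta_oxidation
SYNFATG088	M00087_beta_oxidation
SYNFATG089	M00087_beta_oxidation
SYNFATG090	M00087_beta_oxidation
SYNFATG091	M00087_beta_oxidation
SYNFATG092	M00087_beta_oxidation
SYNFATG093	M00087_beta_oxidation
SYNFATG094	M00087_beta_oxidation
SYNFATG095	M00087_beta_oxidation
SYNFATG096	M00087_beta_oxidation
SYNFATG097	M00087_beta_oxidation
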