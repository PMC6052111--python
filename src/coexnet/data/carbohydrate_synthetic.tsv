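gene_id	subpathway
SYNCARG001	M00001_glycolysis
SYNCARG002	M00001_glycolysis
SYNCARG003	M00001_glycolysis
SYNCARG004	M00001_glycolysis
SYNCARG005	M00001_glycolysis
SYNCARG006	M00001_glycolysis
SYNCARG007	M00001_glycolysis
SYNCARG008	M00001_glycolysis
SYNCARG009	M00001_glycolysis
SYNCARG010	M00001_glycolysis
SYNCARG011	M00001_glycolysis
SYNCARG012	M00001_glycolysis
SYNCARG013	M00001_glycolysis
SYNCARG014	M00001_glycolysis
SYNCARG015	M00001_glycolysis
SYNCARG016	M00001_glycolysis
SYNCARG017	M00001_glycolysis
SYNCARG018	M00001_glycolysis
SYNCARG019	M00001_glycolysis
SYNCARG020	M00001_glycolysis
SYNCARG021	M00001_glycolysis
SYNCARG022	M00001_glycolysis
SYNCARG023	M00001_glycolysis
SYNCARG024	M00001_glycolysis
SYNCARG025	M00001_glycolysis
SYNCARG026	M00001_glycolysis
SYNCARG027	M00001_glycolysis
SYNCARG028	M00001_glycolysis
SYNCARG029	M00001_glycolysis
SYNCARG030	M00001_glycolysis
SYNCARG031	M00001_glycolysis
SYNCARG032	M00001_glycolysis
SYNCARG033	M00001_glycolysis
SYNCARG034	M00001_glycolysis
SYNCARG035	M00001_glycolysis
SYNCARG036	M00002_glycolysis_core
SYNCARG037	M00002_glycolysis_core
SYNCARG038	M00002_glycolysis_core
SYNCARG039	M00002_glycolysis_core
SYNCARG040	M00002_glycolysis_core
SYNCARG041	M00002_glycolysis_core
SYNCARG042	M00002_glycolysis_core
SYNCARG043	M00002_glycolysis_core
SYNCARG044	M00002_glycolysis_core
SYNCARG045	M00002_glycolysis_core
SYNCARG046	M00002_glycolysis_core
SYNCARG047	M00002_glycolysis_core
SYNCARG048	M00002_glycolysis_core
SYNCARG049	M00002_glycolysis_core
SYNCARG050	M00002_glycolysis_core
SYNCARG051	M00002_glycolysis_core
SYNCARG052	M00002_glycolysis_core
SYNCARG053	M00002_glycolysis_core
SYNCARG054	M00002_glycolysis_core
SYNCARG055	M00002_glycolysis_core
SYNCARG056	M00003_gluconeogenesis
SYNCARG057	M00003_gluconeogenesis
SYNCARG058	M00003_gluconeogenesis
SYNCARG059	M00003_gluconeogenesis
SYNCARG060	M00003_gluconeogenesis
SYNCARG061	M00003_gluconeogenesis
SYNCARG062	M00003_gluconeogenesis
SYNCARG063	M00003_gluconeogenesis
SYNCARG064	M00003_gluconeogenesis
SYNCARG065	M00003_gluconeogenesis
SYNCARG066	M00003_gluconeogenesis
SYNCARG067	M00003_gluconeogenesis
SYNCARG068	M00003_gluconeogenesis
SYNCARG069	M00003_gluconeogenesis
SYNCARG070	M00003_gluconeogenesis
SYNCARG071	M00003_gluconeogenesis
SYNCARG072	M00003_gluconeogenesis
SYNCARG073	M00003_gluconeogenesis
SYNCARG074	M00003_gluconeogenesis
SYNCARG075	M00003_gluconeogenesis
SYNCARG076	M00003_gluconeogenesis
SYNCARG077	M00003_gluconeogenesis
SYNCARG078	M00003_gluconeogenesis
SYNCARG079	M00003_gluconeogenesis
SYNCARG080	M00003_gluconeogenesis
SYNCARG081	M00003_gluconeogenesis
SYNCARG082	M00003_gluconeogenesis
SYNCARG083	M00003_gluconeogenesis
SYNCARG084	M00307_pyruvate_oxidation
SYNCARG085	M00307_pyruvate_oxidation
SYNCARG086	M00307_pyruvate_oxidation
SYNCARG087	M00307_pyruvate_oxidation
SYNCARG088	M00307_pyruvate_oxidation
SYNCARG089	M00307_pyruvate_oxidation
SYNCARG090	M00307_pyruvate_oxidation
SYNCARG091	M00307_pyruvate_oxidation
SYNCARG092	M00307_pyruvate_oxidation
SYNCARG093	M00307_pyruvate_oxidation
SYNCARG094	M00307_pyruvate_oxidation
SYNCARG095	M00307_pyruvate_oxidation
SYNCARG096	M00307_pyruvate_oxidation
SYNCARG097	M00307_pyruvate_oxidation
SYNCARG098	M00307_pyruvate_oxidation
SYNCARG099	M00307_pyruvate_oxidation
SYNCARG100	M00307_pyruvate_oxidation
SYNCARG101	M00307_pyruvate_oxidation
SYNCARG102	M00307_pyruvate_oxidation
SYNCARG103	M00307_pyruvate_oxidation
SYNCARG104	M00307_pyruvate_oxidation
SYNCARG105	M00307_pyruvate_oxidation
SYNCARG106	M00010_citrate_cycle
SYNCARG107	M00010_citrate_cycle
SYNCARG108	M00010_citrate_cycle
SYNCARG109	M00010_citrate_cycle
SYNCARG110	M00010_citrate_cycle
SYNCARG111	M00010_citrate_cycle
SYNCARG112	M00010_citrate_cycle
SYNCARG113	M00010_citrate_cycle
SYNCARG114	M00010_citrate_cycle
SYNCARG115	M00010_citrate_cycle
SYNCARG116	M00010_citrate_cycle
SYNCARG117	M00010_citrate_cycle
SYNCARG118	M00010_citrate_cycle
SYNCARG119	M00010_citrate_cycle
SYNCARG120	M00010_citrate_cycle
SYNCARG121	M00010_citrate_cycle
SYNCARG122	M00010_citrate_cycle
SYNCARG123	M00010_citrate_cycle
SYNCARG124	M00010_citrate_cycle
SYNCARG125	M00010_citrate_cycle
SYNCARG126	M00010_citrate_cycle
SYNCARG127	M00010_citrate_cycle
SYNCARG128	M00010_citrate_cycle
SYNCARG129	M00010_citrate_cycle
SYNCARG130	M00010_citrate_cycle
SYNCARG131	M00010_citrate_cycle
SYNCARG132	M00010_citrate_cycle
SYNCARG133	M00010_citrate_cycle
SYNCARG134	M00010_citrate_cycle
SYNCARG135	M00010_citrate_cycle
SYNCARG136	M00010_citrate_cycle
SYNCARG137	M00010_citrate_cycle
SYNCARG138	M00010_citrate_cycle
SYNCARG139	M00010_citrate_cycle
SYNCARG140	M00010_citrate_cycle
SYNCARG141	M00010_citrate_cycle
SYNCARG142	M00010_citrate_cycle
SYNCARG143	M00010_citrate_cycle
SYNCARG144	M00010_citrate_cycle
SYNCARG145	M00010_citrate_cycle
SYNCARG146	M00004_pentose_phosphate
SYNCARG147	M00004_pentose_phosphate
SYNCARG148	M00004_pentose_phosphate
SYNCARG149	M00004_pentose_phosphate
SYNCARG150	M00004_pentose_phosphate
SYNCARG151	M00004_pentose_phosphate
SYNCARG152	M00004_pentose_phosphate
SYNCARG153	M00004_pentose_phosphate
SYNCARG154	M00004_pentose_phosphate
SYNCARG155	M00004_pentose_phosphate
SYNCARG156	M00004_pentose_phosphate
SYNCARG157	M00004_pentose_phosphate
SYNCARG158	M00004_pentose_phosphate
SYNCARG159	M00004_pentose_phosphate
SYNCARG160	M00004_pentose_phosphate
SYNCARG161	M00004_pentose_phosphate
SYNCARG162	M00004_pentose_phosphate
SYNCARG163	M00004_pentose_phosphate
SYNCARG164	M00004_pentose_phosphate
SYNCARG165	M00004_pentose_phosphate
SYNCARG166	M00004_pentose_phosphate
SYNCARG167	M00004_pentose_phosphate
SYNCARG168	M00004_pentose_phosphate
SYNCARG169	M00004_pentose_phosphate
SYNCARG170	M00004_pentose_phosphate
SYNCARG171	M00006_ppp_oxidative
SYNCARG172	M00006_ppp_oxidative
SYNCARG173	M00006_ppp_oxidative
SYNCARG174	M00006_ppp_oxidative
SYNCARG175	M00006_ppp_oxidative
SYNCARG176	M00006_ppp_oxidative
SYNCARG177	M00006_ppp_oxidative
SYNCARG178	M00006_ppp_oxidative
SYNCARG179	M00006_ppp_oxidative
SYNCARG180	M00006_ppp_oxidative
SYNCARG181	M00006_ppp_oxidative
SYNCARG182	M00006_ppp_oxidative
SYNCARG183	M00006_ppp_oxidative
SYNCARG184	M00006_ppp_oxidative
SYNCARG185	M00006_ppp_oxidative
SYNCARG186	M00006_ppp_oxidative
SYNCARG187	M00007_ppp_nonoxidative
SYNCARG188	M00007_ppp_nonoxidative
SYNCARG189	M00007_ppp_nonoxidative
SYNCARG190	M00007_ppp_nonoxidative
SYNCARG191	M00007_ppp_nonoxidative
SYNCARG192	M00007_ppp_nonoxidative
SYNCARG193	M00007_ppp_nonoxidative
SYNCARG194	M00007_ppp_nonoxidative
SYNCARG195	M00007_ppp_nonoxidative
SYNCARG196	M00007_ppp_nonoxidative
SYNCARG197	M00007_ppp_nonoxidative
SYNCARG198	M00007_ppp_nonoxidative
SYNCARG199	M00007_ppp_nonoxidative
SYNCARG200	M00007_ppp_nonoxidative
SYNCARG201	M00007_ppp_nonoxidative
SYNCARG202	M00007_ppp_nonoxidative
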