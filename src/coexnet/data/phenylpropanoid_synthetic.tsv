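gene_id	subpathway
SYNPHEG001	core_phenylpropanoid
SYNPHEG002	core_phenylpropanoid
SYNPHEG003	core_phenylpropanoid
SYNPHEG004	flavonoids
SYNPHEG005	flavonoids
SYNPHEG006	flavonoids
SYNPHEG007	flavonoids
SYNPHEG008	flavonoids
SYNPHEG009	flavonoids
SYNPHEG010	flavonoids
SYNPHEG011	flavonoids
SYNPHEG012	flavonoids
SYNPHEG013	flavonoids
SYNPHEG014	flavonoids
SYNPHEG015	flavonoids
SYNPHEG016	flavonoids
SYNPHEG017	flavonoids
SYNPHEG018	flavonoids
SYNPHEG019	flavonoids
SYNPHEG020	flavonoids
SYNPHEG021	flavonoids
SYNPHEG022	monolignols
SYNPHEG023	monolignols
SYNPHEG024	monolignols
SYNPHEG025	monolignols
SYNPHEG026	monolignols
SYNPHEG027	monolignols
SYNPHEG028	monolignols
SYNPHEG029	monolignols
SYNPHEG030	monolignols
SYNPHEG031	monolignols
SYNPHEG032	monolignols
SYNPHEG033	monolignols
SYNPHEG034	monolignols
SYNPHEG035	monolignols
SYNPHEG036	phenolamides
SYNPHEG037	phenolamides
SYNPHEG038	phenolamides
SYNPHEG039	phenolamides
SYNPHEG040	phenolamides
SYNPHEG041	phenolamides
SYNPHEG042	phenolamides
SYNPHEG043	phenolamides
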