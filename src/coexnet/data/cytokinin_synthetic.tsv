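gene_id	subpathway
SYNCKXG001	receptor
SYNCKXG002	receptor
SYNCKXG003	receptor
SYNCKXG004	receptor
SYNCKXG005	receptor
SYNCKXG006	transducer
SYNCKXG007	transducer
SYNCKXG008	transducer
SYNCKXG009	transducer
SYNCKXG010	transducer
SYNCKXG011	transducer
SYNCKXG012	type_A_response_regulator
SYNCKXG013	type_A_response_regulator
SYNCKXG014	type_A_response_regulator
SYNCKXG015	type_A_response_regulator
SYNCKXG016	type_A_response_regulator
SYNCKXG017	type_A_response_regulator
SYNCKXG018	type_A_response_regulator
SYNCKXG019	type_A_response_regulator
SYNCKXG020	type_A_response_regulator
SYNCKXG021	type_A_response_regulator
SYNCKXG022	type_B_response_regulator
SYNCKXG023	type_B_response_regulator
SYNCKXG024	type_B_response_regulator
SYNCKXG025	type_B_response_regulator
SYNCKXG026	type_B_response_regulator
SYNCKXG027	type_B_response_regulator
SYNCKXG028	type_B_response_regulator
SYNCKXG029	type_B_response_regulator
SYNCKXG030	type_B_response_regulator
SYNCKXG031	type_B_response_regulator
SYNCKXG032	type_B_response_regulator
SYNCKXG033	type_B_response_regulator
SYNCKXG034	type_C_response_regulator
SYNCKXG035	type_C_response_regulator
SYNCKXG036	type_C_response_regulator
SYNCKXG037	type_C_response_regulator
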