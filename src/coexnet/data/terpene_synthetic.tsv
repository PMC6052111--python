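gene_id	subpathway
SYNTERG001	M00095_mevalonate
SYNTERG002	M00095_mevalonate
SYNTERG003	M00095_mevalonate
SYNTERG004	M00095_mevalonate
SYNTERG005	M00095_mevalonate
SYNTERG006	M00095_mevalonate
SYNTERG007	M00095_mevalonate
SYNTERG008	M00095_mevalonate
SYNTERG009	M00095_mevalonate
SYNTERG010	M00095_mevalonate
SYNTERG011	M00095_mevalonate
SYNTERG012	M00095_mevalonate
SYNTERG013	M00096_methylerythritol
SYNTERG014	M00096_methylerythritol
SYNTERG015	M00096_methylerythritol
SYNTERG016	M00096_methylerythritol
SYNTERG017	M00096_methylerythritol
SYNTERG018	M00096_methylerythritol
SYNTERG019	M00096_methylerythritol
SYNTERG020	M00096_methylerythritol
SYNTERG021	M00096_methylerythritol
SYNTERG022	M00096_methylerythritol
SYNTERG023	M00096_methylerythritol
SYNTERG024	M00366_c10_c20_isoprenoid
SYNTERG025	M00366_c10_c20_isoprenoid
SYNTERG026	M00366_c10_c20_isoprenoid
SYNTERG027	M00366_c10_c20_isoprenoid
SYNTERG028	M00366_c10_c20_isoprenoid
SYNTERG029	M00366_c10_c20_isoprenoid
SYNTERG030	M00366_c10_c20_isoprenoid
SYNTERG031	M00366_c10_c20_isoprenoid
SYNTERG032	M00366_c10_c20_isoprenoid
SYNTERG033	M00366_c10_c20_isoprenoid
SYNTERG034	M00366_c10_c20_isoprenoid
SYNTERG035	M00366_c10_c20_isoprenoid
SYNTERG036	M00097_beta_carotene
SYNTERG037	M00097_beta_carotene
SYNTERG038	M00097_beta_carotene
SYNTERG039	M00097_beta_carotene
SYNTERG040	M00097_beta_carotene
SYNTERG041	M00097_beta_carotene
SYNTERG042	M00097_beta_carotene
SYNTERG043	M00097_beta_carotene
SYNTERG044	M00097_beta_carotene
SYNTERG045	M00097_beta_carotene
SYNTERG046	M00372_abscisic_acid
SYNTERG047	M00372_abscisic_acid
SYNTERG048	M00372_abscisic_acid
SYNTERG049	M00372_abscisic_acid
SYNTERG050	M00372_abscisic_acid
SYNTERG051	M00372_abscisic_acid
SYNTERG052	M00372_abscisic_acid
SYNTERG053	M00372_abscisic_acid
SYNTERG054	M00371_phytosterol
SYNTERG055	M00371_phytosterol
SYNTERG056	M00371_phytosterol
SYNTERG057	M00371_phytosterol
SYNTERG058	M00371_phytosterol
SYNTERG059	M00371_phytosterol
SYNTERG060	M00371_phytosterol
SYNTERG061	M00371_phytosterol
SYNTERG062	M00371_phytosterol
SYNTERG063	M00371_phytosterol
SYNTERG064	M00371_phytosterol
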