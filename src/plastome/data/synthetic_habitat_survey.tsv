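species_id	habitat	pbsA
Bangia atropurpurea	freshwater	1
Sheathia arcuata	freshwater	1
Paralemanea sp.	freshwater	1
Sirodotia delicatula	freshwater	1
Kumanoa americana	freshwater	0
Kumanoa ambigua	freshwater	0
Kumanoa mahlacensis	freshwater	0
Thorea hispida	freshwater	0
Batrachospermum viride-brasiliense	freshwater	0
Batrachospermum macrosporum	freshwater	0
Hildenbrandia rivularis	freshwater	0
Cyanidioschyzon merolae	freshwater	0
Cyanidium caldarium	freshwater	0
Galdieria sulphuraria	freshwater	0
Galdieria phlegrea	freshwater	0
Compsopogon caeruleus	freshwater	0
Palmaria palmata	marine	1
marine_sp_002	marine	1
marine_sp_003	marine	1
marine_sp_004	marine	1
marine_sp_005	marine	1
marine_sp_006	marine	1
marine_sp_007	marine	1
marine_sp_008	marine	1
marine_sp_009	marine	1
marine_sp_010	marine	1
marine_sp_011	marine	1
marine_sp_012	marine	1
marine_sp_013	marine	1
marine_sp_014	marine	1
marine_sp_015	marine	1
marine_sp_016	marine	1
marine_sp_017	marine	1
marine_sp_018	marine	1
marine_sp_019	marine	1
marine_sp_020	marine	1
marine_sp_021	marine	1
marine_sp_022	marine	1
marine_sp_023	marine	1
marine_sp_024	marine	1
marine_sp_025	marine	1
marine_sp_026	marine	1
marine_sp_027	marine	1
marine_sp_028	marine	1
marine_sp_029	marine	1
marine_sp_030	marine	1
marine_sp_031	marine	1
marine_sp_032	marine	1
marine_sp_033	marine	1
marine_sp_034	marine	1
marine_sp_035	marine	1
marine_sp_036	marine	1
marine_sp_037	marine	1
marine_sp_038	marine	1
marine_sp_039	marine	1
marine_sp_040	marine	1
marine_sp_041	marine	1
marine_sp_042	marine	1
marine_sp_043	marine	1
marine_sp_044	marine	1
marine_sp_045	marine	1
marine_sp_046	marine	1
marine_sp_047	marine	1
marine_sp_048	marine	1
marine_sp_049	marine	1
marine_sp_050	marine	1
marine_sp_051	marine	1
marine_sp_052	marine	1
marine_sp_053	marine	1
marine_sp_054	marine	1
marine_sp_055	marine	1
marine_sp_056	marine	1
marine_sp_057	marine	1
marine_sp_058	marine	1
marine_sp_059	marine	1
marine_sp_060	marine	1
marine_sp_061	marine	1
marine_sp_062	marine	1
marine_sp_063	marine	1
marine_sp_064	marine	1
marine_sp_065	marine	1
marine_sp_066	marine	1
marine_sp_067	marine	1
marine_sp_068	marine	1
marine_sp_069	marine	1
marine_sp_070	marine	1
marine_sp_071	marine	1
marine_sp_072	marine	1
marine_sp_073	marine	1
marine_sp_074	marine	1
marine_sp_075	marine	1
marine_sp_076	marine	1
marine_sp_077	marine	1
marine_sp_078	marine	1
marine_sp_079	marine	1
marine_sp_080	marine	1
marine_sp_081	marine	1
marine_sp_082	marine	1
marine_sp_083	marine	1
marine_sp_084	marine	1
marine_sp_085	marine	1
marine_sp_086	marine	1
marine_sp_087	marine	1
marine_sp_088	marine	1
marine_sp_089	marine	1
marine_sp_090	marine	1
marine_sp_091	marine	1
marine_sp_092	marine	1
marine_sp_093	marine	1
marine_sp_094	marine	1
marine_sp_095	marine	1
marine_sp_096	marine	1
marine_sp_097	marine	1
marine_sp_098	marine	1
marine_sp_099	marine	1
marine_sp_100	marine	1
marine_sp_101	marine	0
marine_sp_102	marine	0
marine_sp_103	marine	0
marine_sp_104	marine	0
marine_sp_105	marine	0
marine_sp_106	marine	0
marine_sp_107	marine	0
marine_sp_108	marine	0
marine_sp_109	marine	0
brackish_sp_001	brackish	1
brackish_sp_002	brackish	1
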