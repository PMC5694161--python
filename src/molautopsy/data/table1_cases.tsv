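case_id	age	sex	race	fa_status	fa_summary	ma_status	likely_causal_variants	variant_phenotype
MA00072	2 months	Male	Biracial	Negative	SIDS (bronchopneumonia following resuscitation for SIDS)	Negative
MA00002	3 months	Male	White	Negative	SIDS	Negative
MA00005	3 months	Male	Asian	Negative	SIDS	Negative
MA00011	3 months	Male	White	Negative	SIDS	Positive	NM_001035.2(RYR2):c.7601T>C (p.Leu2534Pro)	CPVT
MA00019	3 months	Male	Hispanic	Negative	SIDS	Positive	NM_002977.3(SCN9A):c.2971G>T (p.Val991Leu)	Epilepsy
MA00056	8 months	Female	Hispanic	Negative	SIDS	Negative
MA00017	9 months	Male	African-American	Negative	SIDS (hippocampal abnormality/recent history of possible seizures)	Positive	NM_001293307.2(SCN10A):c.742G>C (p.Asp248His)	BrS
MA00007	10 months	Male	White	Negative	SIDS	Negative
MA02005	1	Male	White	Negative	SIDS	Positive	NM_005477.2(HCN4):c.2275G>A (p.Val759Ile)	BrS
MA00029	2	Female	Hispanic	Positive	Aneurysm (rupture of left middle cerebral artery aneurysm)	Negative
MA02009	2	Female	NA	Negative	SIDS (febrile seizure)	Negative
MA02001	9	Male	NA	Negative	SUXD	Negative
MA02008	10	Female	NA	Negative	Complication from chronic lymphocytic thyroiditis with T3 thyrotoxicosis	Negative
MA02004	15	Male	White	Positive	Borderline cardiomegaly/valve dilation	Negative
MA02007	17	Female	NA	Positive	HCM	Positive	NM_000257.3(MYH7):c.4377G>T p.K1459N	HCM
MA04006	17	Male	White	Negative	-	Negative
MA00024	17/24	Males	Hispanic	Positive/Negative	HCM/-	Negative/negative
MA00080	19	Female	African-American	Negative	SUDEP	Negative
MA00025	21	Male	NA	Negative	SUXD	Negative
MA02003	21	Male	NA	Negative	-	Negative
MA00016	22	Male	Hispanic	Positive	HCM	Negative
MA00081	22	Male	White	Negative	SUXD	Negative
MA03003	23	Female	Asian	Positive	HCM/increased fatty infiltration of RV/enlarged heart	Negative
MA04004	24	Male	White	Positive	RV cardiomyopathy/fibrofatty replacement RV/dilated RV	Negative
MA04005	24	Female	White	Negative	Moderate mitral valve prolapse/fibrosis LV	Negative
MA00038	25	Female	White	Positive	ARVC/D	Positive	NM_004572.3(PKP2):c.1132C>T (p.Gln378Ter)	ARVC/D
MA00098	25	Male	White	Positive	DCM	Negative
MA00066	27	Female	African-American	Positive	Aneurysm (ruptured cerebral artery)	Negative
MA02010	27	Male	African-American	Negative	SUXD/moderate RV dilation	Positive	NM_000371.3(TTR):c.424G>A (p.Val142Ile)	Amyloidosis
MA00018	28	Male	African-American	Positive	HCM	Negative
MA02002	29	Male	White	Positive	Coronary artery atherosclerosis	Positive	NM_017636.3(TRPM4):c.1575G>A (p.Trp525Ter)	Progressive familial heart block
MA00052	30	Male	Hispanic	Positive	SCD/myocardial ischemia/cardiac arteriolosclerosis and apparent vasospasm	Positive	NM_005751.4(AKAP9):c.11272C>T (p.Arg3758Cys)	LQTS
MA00068	30	Male	White	Positive	DCM	Negative
MA00003	31	Male	White	Negative	-	Negative
MA00047	32	Male	Hispanic	Negative	SUXD	Negative
MA01001	32	Male	White	Positive	HCM	Positive	NM_002471.3(MYH6):c.3010G>T (p.Ala1004Ser)	HCM
MA00027	33	Male	White	Positive	SUD (arteriosclerotic cardiovascular disease/thrombotic occlusion of left anterior descending artery)	Positive	NM_000361.2(THBD):c.302G>T (p.Arg101Leu)	Thrombophilia
MA00033	34	Female	Hispanic	Positive	Aneurysm (probable ruptured berry aneurysm/acute non-traumatic subarachnoid hemorrhage/HCM/fatty change of liver)	Negative
MA00054	36	Female	Asian	Positive	SCD/acute coronary artery dissection/eosinophilic coronary arteritis	Negative
MA03006	36	Male	White	Positive	Coronary artery atherosclerosis	Negative
MA00055	37	Female	White	Positive	HCM and ischemic brain injury	Negative
MA04007	37	Female	White	Positive	Healed viral myocarditis/RV cardiomyopathy	Positive	NM_004415.3(DSP):c.268C>T (p.Gln90Ter)	ARVC/D
MA00076	38	Female	White	Negative	-	Negative
MA00082	39	Female	White	Negative	SUDEP	Negative
MA00032	40	Male	White	Positive	Hypertensive and atherosclerotic cardiovascular disease/hepatomegaly	Negative
MA00048	41	Female	White	Positive	Hypertensive cardiovascular disease/acute left basal ganglia hemorrhage (stroke)	Negative
MA02006	41	Female	White	Positive	HCM/mild myocardial fibrosis	Negative
MA00046	43	Male	Hispanic	Positive	HCM (mild hypertensive cardiomyopathy and obesity)	Positive	NM_001035.2(RYR2):c.9673G>A (p.Gly3225Ser)	CPVT
MA00001	44	Male	White	Positive	HCM	Positive	NM_017636.3(TRPM4):c.1697C>T (p.Ala566Val)/NM_006514.3(SCN10A):c.3704C>T (p.Ala1235Val)	Progressive familial heart block/BrS
MA02000	44	Female	White	Positive	DCM	Negative
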