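key	term_id	name	n_all	n_cluster1	n_cluster2	n_cluster3
TOF	PT:0000024	Tetralogy of Fallot	122	116	1	5
VSD	PT:0000020	Ventricular septal defect	512	482	9	21
ASD	PT:0000021	Atrial septal defect	224	161	54	9
PDA	PT:0000033	Patent ductus arteriosus	490	392	89	9
PFO	PT:0000022	Patent foramen ovale	211	167	44	0
RVH	PT:0000025	Right ventricular hypertrophy	203	186	9	8
ACA	PT:0000034	Aortopulmonary collateral arteries	281	267	1	13
HRH	PT:0000031	Hypoplastic right heart	44	7	35	2
SV	PT:0000027	Single ventricle	45	30	8	7
DEX	PT:0000059	Dextrocardia	44	29	8	7
CA	PT:0000056	Common atrium	25	11	6	8
LSVC	PT:0000036	Persistent left superior vena cava	93	82	3	8
PAH1	PT:0000039	Pulmonary arterial hypertension	6	5	1	0
PAH2	PT:0000040	Pulmonary artery hypoplasia	6	5	0	1
PAS	PT:0000041	Pulmonary artery stenosis	49	33	14	1
RAA	PT:0000042	Right aortic arch	49	45	0	4
DAA	PT:0000043	Double aortic arch	3	3	0	0
AR_AI	PT:0000044	Aortic regurgitation	16	14	2	0
AVS	PT:0000045	Aortic valve stenosis	1	1	0	0
BAV	PT:0000046	Bicuspid aortic valve	3	2	1	0
TR_TI	PT:0000047	Tricuspid regurgitation	99	33	64	2
DTV	PT:0000048	Dysplastic tricuspid valve	17	2	15	0
TS	PT:0000049	Tricuspid stenosis	19	4	15	0
TA	PT:0000050	Tricuspid atresia	18	2	12	4
EATV	PT:0000051	Ebstein anomaly of the tricuspid valve	2	1	1	0
MR_MI	PT:0000052	Mitral regurgitation	16	11	5	0
MA	PT:0000053	Mitral atresia	3	1	1	1
DORV	PT:0000032	Double outlet right ventricle	20	17	1	2
RVD	PT:0000028	Right ventricular dilatation	6	6	0	0
RVOTO	PT:0000029	Right ventricular outflow tract obstruction	6	5	0	1
HLH	PT:0000030	Hypoplastic left heart	5	2	1	2
LVH	PT:0000026	Left ventricular hypertrophy	3	1	1	1
RAE	PT:0000057	Right atrial enlargement	8	4	3	1
MESO	PT:0000060	Mesocardia	11	9	1	1
ASOCS	PT:0000061	Abnormal spatial orientation of the cardiac segments	23	18	3	2
ACD_ECD	PT:0000023	Atrioventricular canal defect	22	15	4	3
ACAM1	PT:0000058	Abnormal cardiac atrium shape	6	2	3	1
AAC	PT:0000062	Abnormal atrioventricular connection	20	15	1	4
AAVM	PT:0000054	Abnormal atrioventricular valve morphology	20	13	5	2
PI	PT:0000055	Pulmonary valve insufficiency	3	1	2	0
APV	PT:0000037	Abnormality of the pulmonary veins	15	8	5	2
TGA	PT:0000035	Transposition of the great arteries	75	64	7	4
ACAM2	PT:0000038	Abnormal coronary artery morphology	20	14	3	3
ATW	PT:0000063	Abnormal T-wave	27	12	6	9
ASTS	PT:0000064	Abnormal ST segment	14	6	5	3
RBBB	PT:0000065	Right bundle branch block	20	11	3	6
PVC_VPB	PT:0000066	Premature ventricular contraction	1	0	1	0
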