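format-version: 1.2
ontology: toy-cardio
remark: synthetic toy cardiovascular phenotype ontology (fixture; not HPO)

[Term]
id: PT:0000001
name: Cardiovascular abnormality

[Term]
id: PT:0000002
name: Abnormal cardiac septum morphology
is_a: PT:0000001 ! Cardiovascular abnormality

[Term]
id: PT:0000003
name: Abnormal heart valve morphology
is_a: PT:0000001 ! Cardiovascular abnormality

[Term]
id: PT:0000004
name: Abnormal ventricular morphology
is_a: PT:0000001 ! Cardiovascular abnormality

[Term]
id: PT:0000005
name: Abnormal great vessel morphology
is_a: PT:0000001 ! Cardiovascular abnormality

[Term]
id: PT:0000006
name: Abnormal atrial morphology
is_a: PT:0000001 ! Cardiovascular abnormality

[Term]
id: PT:0000007
name: Abnormal cardiac electrophysiology
is_a: PT:0000001 ! Cardiovascular abnormality

[Term]
id: PT:0000008
name: Abnormal cardiac situs or position
is_a: PT:0000001 ! Cardiovascular abnormality

[Term]
id: PT:0000009
name: Abnormal tricuspid valve morphology
is_a: PT:0000003 ! Abnormal heart valve morphology

[Term]
id: PT:0000010
name: Abnormal mitral valve morphology
is_a: PT:0000003 ! Abnormal heart valve morphology

[Term]
id: PT:0000011
name: Abnormal aortic valve morphology
is_a: PT:0000003 ! Abnormal heart valve morphology

[Term]
id: PT:0000012
name: Abnormal pulmonary artery morphology
is_a: PT:0000005 ! Abnormal great vessel morphology

[Term]
id: PT:0000013
name: Abnormal aortic arch morphology
is_a: PT:0000005 ! Abnormal great vessel morphology

[Term]
id: PT:0000020
name: Ventricular septal defect
alt_id: PT:0000120
is_a: PT:0000002 ! Abnormal cardiac septum morphology

[Term]
id: PT:0000021
name: Atrial septal defect
is_a: PT:0000002 ! Abnormal cardiac septum morphology
is_a: PT:0000006 ! Abnormal atrial morphology

[Term]
id: PT:0000022
name: Patent foramen ovale
is_a: PT:0000002 ! Abnormal cardiac septum morphology

[Term]
id: PT:0000023
name: Atrioventricular canal defect
is_a: PT:0000002 ! Abnormal cardiac septum morphology
is_a: PT:0000003 ! Abnormal heart valve morphology

[Term]
id: PT:0000024
name: Tetralogy of Fallot
is_a: PT:0000004 ! Abnormal ventricular morphology
is_a: PT:0000002 ! Abnormal cardiac septum morphology

[Term]
id: PT:0000025
name: Right ventricular hypertrophy
is_a: PT:0000004 ! Abnormal ventricular morphology

[Term]
id: PT:0000026
name: Left ventricular hypertrophy
is_a: PT:0000004 ! Abnormal ventricular morphology

[Term]
id: PT:0000027
name: Single ventricle
is_a: PT:0000004 ! Abnormal ventricular morphology

[Term]
id: PT:0000028
name: Right ventricular dilatation
is_a: PT:0000004 ! Abnormal ventricular morphology

[Term]
id: PT:0000029
name: Right ventricular outflow tract obstruction
is_a: PT:0000004 ! Abnormal ventricular morphology

[Term]
id: PT:0000030
name: Hypoplastic left heart
is_a: PT:0000004 ! Abnormal ventricular morphology

[Term]
id: PT:0000031
name: Hypoplastic right heart
is_a: PT:0000004 ! Abnormal ventricular morphology

[Term]
id: PT:0000032
name: Double outlet right ventricle
is_a: PT:0000004 ! Abnormal ventricular morphology

[Term]
id: PT:0000033
name: Patent ductus arteriosus
is_a: PT:0000005 ! Abnormal great vessel morphology

[Term]
id: PT:0000034
name: Aortopulmonary collateral arteries
is_a: PT:0000005 ! Abnormal great vessel morphology

[Term]
id: PT:0000035
name: Transposition of the great arteries
is_a: PT:0000005 ! Abnormal great vessel morphology

[Term]
id: PT:0000036
name: Persistent left superior vena cava
is_a: PT:0000005 ! Abnormal great vessel morphology

[Term]
id: PT:0000037
name: Abnormality of the pulmonary veins
is_a: PT:0000005 ! Abnormal great vessel morphology

[Term]
id: PT:0000038
name: Abnormal coronary artery morphology
is_a: PT:0000005 ! Abnormal great vessel morphology

[Term]
id: PT:0000039
name: Pulmonary arterial hypertension
is_a: PT:0000012 ! Abnormal pulmonary artery morphology

[Term]
id: PT:0000040
name: Pulmonary artery hypoplasia
is_a: PT:0000012 ! Abnormal pulmonary artery morphology

[Term]
id: PT:0000041
name: Pulmonary artery stenosis
is_a: PT:0000012 ! Abnormal pulmonary artery morphology

[Term]
id: PT:0000042
name: Right aortic arch
is_a: PT:0000013 ! Abnormal aortic arch morphology

[Term]
id: PT:0000043
name: Double aortic arch
is_a: PT:0000013 ! Abnormal aortic arch morphology

[Term]
id: PT:0000044
name: Aortic regurgitation
is_a: PT:0000011 ! Abnormal aortic valve morphology

[Term]
id: PT:0000045
name: Aortic valve stenosis
is_a: PT:0000011 ! Abnormal aortic valve morphology

[Term]
id: PT:0000046
name: Bicuspid aortic valve
is_a: PT:0000011 ! Abnormal aortic valve morphology

[Term]
id: PT:0000047
name: Tricuspid regurgitation
is_a: PT:0000009 ! Abnormal tricuspid valve morphology

[Term]
id: PT:0000048
name: Dysplastic tricuspid valve
is_a: PT:0000009 ! Abnormal tricuspid valve morphology

[Term]
id: PT:0000049
name: Tricuspid stenosis
is_a: PT:0000009 ! Abnormal tricuspid valve morphology

[Term]
id: PT:0000050
name: Tricuspid atresia
is_a: PT:0000009 ! Abnormal tricuspid valve morphology

[Term]
id: PT:0000051
name: Ebstein anomaly of the tricuspid valve
is_a: PT:0000009 ! Abnormal tricuspid valve morphology

[Term]
id: PT:0000052
name: Mitral regurgitation
is_a: PT:0000010 ! Abnormal mitral valve morphology

[Term]
id: PT:0000053
name: Mitral atresia
is_a: PT:0000010 ! Abnormal mitral valve morphology

[Term]
id: PT:0000054
name: Abnormal atrioventricular valve morphology
is_a: PT:0000003 ! Abnormal heart valve morphology

[Term]
id: PT:0000055
name: Pulmonary valve insufficiency
is_a: PT:0000003 ! Abnormal heart valve morphology

[Term]
id: PT:0000056
name: Common atrium
is_a: PT:0000006 ! Abnormal atrial morphology

[Term]
id: PT:0000057
name: Right atrial enlargement
is_a: PT:0000006 ! Abnormal atrial morphology

[Term]
id: PT:0000058
name: Abnormal cardiac atrium shape
is_a: PT:0000006 ! Abnormal atrial morphology

[Term]
id: PT:0000059
name: Dextrocardia
is_a: PT:0000008 ! Abnormal cardiac situs or position

[Term]
id: PT:0000060
name: Mesocardia
is_a: PT:0000008 ! Abnormal cardiac situs or position

[Term]
id: PT:0000061
name: Abnormal spatial orientation of the cardiac segments
is_a: PT:0000008 ! Abnormal cardiac situs or position

[Term]
id: PT:0000062
name: Abnormal atrioventricular connection
is_a: PT:0000001 ! Cardiovascular abnormality

[Term]
id: PT:0000063
name: Abnormal T-wave
is_a: PT:0000007 ! Abnormal cardiac electrophysiology

[Term]
id: PT:0000064
name: Abnormal ST segment
is_a: PT:0000007 ! Abnormal cardiac electrophysiology

[Term]
id: PT:0000065
name: Right bundle branch block
is_a: PT:0000007 ! Abnormal cardiac electrophysiology

[Term]
id: PT:0000066
name: Premature ventricular contraction
is_a: PT:0000007 ! Abnormal cardiac electrophysiology

[Term]
id: PT:0000090
name: Obsolete cardiac chamber anomaly
is_obsolete: true
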