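aa	hydrophobicity_1mrsa	changeability	recruitment_rank	cost_atp	essential_animal
A	0.595	0.977	2	11.7	0
C	0.732	0.773	16	24.7	0
D	0.350	1.060	3	12.7	0
E	0.320	1.076	7	15.3	0
F	0.740	0.834	17	52.0	1
G	0.480	0.811	1	11.7	0
H	0.515	0.966	14	38.3	1
I	0.750	1.014	12	32.3	1
K	0.305	1.048	15	30.3	1
L	0.735	0.861	8	27.3	1
M	0.695	1.093	19	34.3	1
N	0.375	1.142	11	14.7	0
P	0.400	1.055	5	20.3	0
Q	0.380	1.097	13	16.3	0
R	0.372	0.906	10	27.3	0
S	0.475	1.225	6	11.7	0
T	0.520	1.206	9	18.7	1
V	0.735	0.973	4	23.3	1
W	0.680	0.531	20	74.3	1
Y	0.610	0.851	18	50.0	0
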