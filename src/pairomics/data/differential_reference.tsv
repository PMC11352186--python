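feature_id	layer	min_p	bh_p	tfc
deoxyadenosine	metabolite	0.0008	0.0557	2.46
shikimate	metabolite	0.0154	0.2114	2.25
indoleacrylic acid	metabolite	0.0302	0.2451	2.02
S-adenosyl-L-homocysteine	metabolite	0.0005	0.0540	1.97
methylnicotinamide	metabolite	0.0481	0.2451	1.84
anthranilate	metabolite	0.0210	0.2451	1.81
1,3-diphopshateglycerate	metabolite	0.0002	0.0418	1.80
N-acetyl spermidine	metabolite	0.0077	0.1290	1.70
glucose-6-phosphate	metabolite	0.0050	0.1175	1.66
hydroxyphenylacetic acid	metabolite	0.0481	0.2451	1.64
7-methylguanosine	metabolite	0.0035	0.1175	1.62
S-ribosyl-L-homocysteine	metabolite	0.0059	0.1175	1.58
fructose-6-phosphate	metabolite	0.0052	0.1175	1.56
SBP	metabolite	0.0481	0.2451	1.49
D-glucono-delta-lactone-6-phosphate	metabolite	0.0481	0.2451	1.48
3-methylphenylacetic acid	metabolite	0.0077	0.1462	1.45
nicotinamide riboside	metabolite	0.0431	0.1462	1.45
1-Methyladenosine	metabolite	0.0135	0.1847	1.45
uracil	metabolite	0.0070	0.1175	1.41
guanine	metabolite	0.0481	0.2451	1.39
uridine	metabolite	0.0054	0.1175	1.37
carbamoyl phosphate	metabolite	0.0240	0.2749	1.33
homoserine	metabolite	0.0481	0.2451	1.32
ribose-phosphate	metabolite	0.0328	0.2451	1.31
acadesine	metabolite	0.0481	0.2451	1.30
N6-Acetyl-L-lysine	metabolite	0.0226	0.2451	1.29
ornithine	metabolite	0.0481	0.2451	1.27
D-gluconate	metabolite	0.0481	0.2451	1.26
kynurenine	metabolite	0.0334	0.2451	1.25
deoxyinosine	metabolite	0.0481	0.2451	1.25
acetyllysine	metabolite	0.0348	0.2451	1.25
D-sedoheptulose-1-7-phosphate	metabolite	0.0160	0.2180	1.25
N-acetyl-glutamate	metabolite	0.0007	0.0632	1.23
aspartate	metabolite	0.0481	0.2451	1.17
2-hydroxygluterate	metabolite	0.0067	0.1175	1.16
Succinate	metabolite	0.0481	0.2451	1.14
phenylpropiolic acid	metabolite	0.0023	0.1023	1.13
2-oxo-4-methylthiobutanoate	metabolite	0.0038	0.1376	1.13
deoxyribose-phosphate	metabolite	0.0342	0.3151	1.13
arginine	metabolite	0.0481	0.2451	1.11
methylmalonic acid	metabolite	0.0033	0.1175	1.10
asparagine	metabolite	0.0154	0.2114	1.09
dGMP	metabolite	0.0290	0.2857	1.01
trehalose-sucrose	metabolite	0.0389	0.2451	0.90
3-hydroxybuterate	metabolite	0.0485	0.3365	-0.81
dTTP	metabolite	0.0432	0.3269	-1.13
alanine	metabolite	0.0481	0.2451	-1.15
dihydroxy-acetone-phosphate	metabolite	0.0481	0.2451	-1.43
2-deoxyglucose-6-phosphate	metabolite	0.0481	0.2451	-1.46
N-Acetylputrescine	metabolite	0.0429	0.3151	-1.54
2,3-Diphosphoglyceric acid	metabolite	0.0154	0.2114	-1.67
PC (36:7e)	lipid	0.038	0.269	1.52
PE (16:1e) (22:6)	lipid	0.038	0.269	1.49
BiotinylPE (32:5)	lipid	0.004	0.269	1.46
PIP2 (31:6e)	lipid	0.002	0.269	1.32
DG (8:0) (12:2)	lipid	0.050	0.377	1.27
DG (4:0) (10:3)	lipid	0.011	0.269	1.20
DG (4:0) (11:3)	lipid	0.038	0.269	1.12
PC (17:0) (14:1)	lipid	0.038	0.269	1.07
PC (16:1e) (18:1)	lipid	0.030	0.377	-0.91
CL (15:0) (18:1) (15:0) (18:1)	lipid	0.030	0.269	-1.16
PE (40:5e)	lipid	0.038	0.269	-1.19
DG (6:0) (11:3)	lipid	0.038	0.269	-1.23
ChE (20:4)	lipid	0.038	0.269	-1.31
DG (18:3e)	lipid	0.038	0.269	-1.33
PI (18:0) (20:4)	lipid	0.038	0.269	-1.38
TG (16:0) (16:0) (17:0)	lipid	0.038	0.269	-1.39
TG (6:0) (6:0) (14:1)	lipid	0.038	0.269	-1.44
TG (12:1e) (6:0) (6:0)	lipid	0.002	0.269	-1.46
PE (18:0) (22:6)	lipid	0.011	0.269	-1.47
CerP (d36:3+O)	lipid	0.016	0.338	-1.53
PE (16:1e) (20:4)	lipid	0.004	0.269	-1.57
PC (32:0e)	lipid	0.038	0.269	-1.62
PC (32:1e)	lipid	0.038	0.269	-1.64
PE (18:0) (20:3)	lipid	0.011	0.269	-1.74
SM (d38:2)	lipid	0.038	0.269	-1.80
PC (35:1)	lipid	0.038	0.269	-2.09
ACAN	protein	0.0126	0.5077	1.79
CFL1	protein	0.0407	0.5077	1.62
CXCL11	protein	0.0465	0.5077	1.46
H2AFZ	protein	0.0191	0.5077	1.44
MUC1	protein	0.0370	0.5077	1.39
NAMPT	protein	0.0287	0.5077	1.36
INS	protein	0.0185	0.5077	1.35
CD97	protein	0.0058	0.5077	1.32
ICOS	protein	0.0275	0.5077	1.31
PARK7	protein	0.0278	0.5077	1.31
FAM107B	protein	0.0279	0.5077	1.29
CD38	protein	0.0478	0.5077	1.29
NGF	protein	0.0079	0.5077	1.20
PPIF	protein	0.0152	0.5077	1.17
THPO	protein	0.0100	0.5077	1.12
DCN	protein	0.0127	0.5077	1.09
MICA	protein	0.0113	0.5077	0.90
HAPLN1	protein	0.0424	0.5077	0.86
PRKCA	protein	0.0351	0.5077	-1.02
PTPN6	protein	0.0440	0.5077	-1.04
IGFBP2	protein	0.0285	0.5077	-1.07
FSTL1	protein	0.0370	0.5077	-1.12
CTSD	protein	0.0208	0.5077	-1.15
PROC	protein	0.0148	0.5077	-1.21
CCL28	protein	0.0086	0.5077	-1.21
CHRDL1	protein	0.0258	0.5077	-1.22
MSN	protein	0.0142	0.5077	-1.24
MMP14	protein	0.0278	0.5077	-1.29
CCL2	protein	0.0300	0.5077	-1.34
CXCL6	protein	0.0167	0.5077	-1.36
GNLY	protein	0.0453	0.5077	-1.43
CTSV	protein	0.0370	0.5077	-1.47
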