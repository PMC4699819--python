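# Intrinsic backbone PPII propensities, Creamer set
# host peptide: Ac-P3XP3GY-NH2
# columns: one-letter code, propensity, provenance (measured|imputed)
# imputations: TRP and TYR assigned the average of the 18 reported values (0.58)
A	0.61	measured
C	0.55	measured
D	0.63	measured
E	0.61	measured
F	0.58	measured
G	0.58	measured
H	0.55	measured
I	0.50	measured
K	0.59	measured
L	0.58	measured
M	0.55	measured
N	0.55	measured
P	0.67	measured
Q	0.66	measured
R	0.61	measured
S	0.58	measured
T	0.53	measured
V	0.49	measured
W	0.58	imputed
Y	0.58	imputed
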