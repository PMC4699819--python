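# Intrinsic backbone PPII propensities, Hilser set
# host peptide: Ac-VP2XVP2R3Y-NH2
# columns: one-letter code, propensity, provenance (measured|imputed)
A	0.37	measured
C	0.25	measured
D	0.30	measured
E	0.42	measured
F	0.17	measured
G	0.13	measured
H	0.20	measured
I	0.39	measured
K	0.56	measured
L	0.24	measured
M	0.36	measured
N	0.27	measured
P	1.00	measured
Q	0.53	measured
R	0.38	measured
S	0.24	measured
T	0.32	measured
V	0.39	measured
W	0.25	measured
Y	0.25	measured
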