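# Intrinsic backbone PPII propensities, Kallenbach set
# host peptide: Ac-G2XG2-NH2
# columns: one-letter code, propensity, provenance (measured|imputed)
# imputations: PRO assigned 1.00 (highest accepted PPII former),
# GLY assigned 0.50 (below the set average, above the set minimum)
A	0.818	measured
C	0.557	measured
D	0.552	measured
E	0.684	measured
F	0.639	measured
G	0.50	imputed
H	0.428	measured
I	0.519	measured
K	0.581	measured
L	0.574	measured
M	0.498	measured
N	0.667	measured
P	1.00	imputed
Q	0.654	measured
R	0.638	measured
S	0.774	measured
T	0.553	measured
V	0.743	measured
W	0.764	measured
Y	0.630	measured
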