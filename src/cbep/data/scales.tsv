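# Six per-residue physicochemical propensity scales, raw published values.
# Columns: amino acid (one-letter), then one column per scale.
# hydrophilicity: Parker et al. 1986 HPLC peptide retention scale
# flexibility: Karplus & Schulz 1985 B-factor-derived backbone flexibility
# accessibility: Emini et al. 1985 surface accessibility probability
# polarity: Grantham 1974 polarity
# exposed_surface: Janin 1979 interior-to-surface transfer propensity
# turns: Chou & Fasman 1978 beta-turn conformational propensity
# Values are min-max normalized to [0, 1] at load time; edit freely to swap scales.
aa	hydrophilicity	flexibility	accessibility	polarity	exposed_surface	turns
A	2.1	1.041	0.815	8.1	0.3	0.66
C	1.4	0.960	0.394	5.5	0.9	1.19
D	10.0	1.033	1.283	13.0	-0.6	1.46
E	7.8	1.094	1.445	12.3	-0.7	0.74
F	-9.2	0.930	0.695	5.2	0.5	0.60
G	5.7	1.142	0.714	9.0	0.3	1.56
H	2.1	0.982	1.180	10.4	-0.1	0.95
I	-8.0	1.002	0.603	5.2	0.7	0.47
K	5.7	1.093	1.545	11.3	-1.8	1.01
L	-9.2	0.967	0.603	4.9	0.5	0.59
M	-4.2	0.947	0.714	5.7	0.4	0.60
N	7.0	1.117	1.296	11.6	-0.5	1.56
P	2.1	1.055	1.236	8.0	-0.3	1.52
Q	6.0	1.165	1.348	10.5	-0.7	0.98
R	4.2	1.038	1.475	10.5	-1.4	0.95
S	6.5	1.169	1.115	9.2	-0.1	1.43
T	5.2	1.073	1.184	8.6	-0.2	0.96
V	-3.7	0.982	0.606	5.9	0.6	0.50
W	-10.0	0.925	0.808	5.4	0.3	0.96
Y	-1.9	0.961	1.089	6.2	-0.4	1.14
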