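# Default per-position weight factors for the class I peptide binding groove.
# Positions listed here are the classical peptide-contact (pseudo-sequence)
# residues lining the A-F pockets; they receive full weight. Positions not
# listed fall back to a small background weight (default 0.1) so the table
# acts as a soft, not hard, contact threshold. Override by supplying your own
# position->weight mapping.
position,weight
7,1.0
9,1.0
24,1.0
45,1.0
59,1.0
62,1.0
63,1.0
66,1.0
67,1.0
69,1.0
70,1.0
73,1.0
74,1.0
76,1.0
77,1.0
80,1.0
81,1.0
84,1.0
95,1.0
97,1.0
99,1.0
114,1.0
116,1.0
118,1.0
143,1.0
147,1.0
150,1.0
152,1.0
156,1.0
158,1.0
159,1.0
163,1.0
167,1.0
171,1.0
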