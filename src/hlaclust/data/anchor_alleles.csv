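# Anchor alleles with their subtype and supertype labels for
# nearest-neighbor clustering. Fully user-replaceable: supply any CSV with
# the same columns to cluster against a different scheme.
allele,subtype,supertype
HLA-A*01:01,A01,A01-A03-A66
HLA-A*03:01,A03,A01-A03-A66
HLA-A*11:01,A03,A01-A03-A66
HLA-A*30:01,A03,A01-A03-A66
HLA-A*66:01,A66,A01-A03-A66
HLA-A*02:01,A02,A02
HLA-A*02:03,A02,A02
HLA-A*02:06,A02,A02
HLA-A*02:07,A02,A02
HLA-A*68:01,A02,A02
HLA-A*24:02,A24,A24
HLA-B*07:02,B07,B07-B35
HLA-B*42:01,B07,B07-B35
HLA-B*35:01,B35,B07-B35
HLA-B*08:01,B08,B08-B18-B39
HLA-B*18:01,B18,B08-B18-B39
HLA-B*39:01,B39,B08-B18-B39
HLA-B*14:02,B14,B14
HLA-B*15:01,B15,B15-B40
HLA-B*40:02,B15,B15-B40
HLA-B*40:01,B40,B15-B40
HLA-B*27:05,B27,B27
HLA-B*44:02,B44,B44
HLA-B*44:03,B44,B44
HLA-B*51:01,B51,B51-B58
HLA-B*57:01,B58,B51-B58
HLA-B*58:01,B58,B51-B58
HLA-C*04:01,C01,C01-C02
HLA-C*05:01,C01,C01-C02
HLA-C*08:02,C01,C01-C02
HLA-B*46:01,C02,C01-C02
HLA-C*06:02,C02,C01-C02
HLA-C*07:01,C07,C07
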