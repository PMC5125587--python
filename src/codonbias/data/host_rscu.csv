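aa,codon,zikv,homo_sapiens,aedes_aegypti,aedes_albopictus
Phe,UUU,1.008,0.87,0.56,0.48
Phe,UUC,0.992,1.13,1.44,1.52
Leu,UUA,0.330,0.39,0.35,0.23
Leu,UUG,1.323,0.73,1.34,1.11
Leu,CUU,0.801,0.73,0.67,0.49
Leu,CUC,1.000,1.21,0.81,0.87
Leu,CUA,0.659,0.40,0.54,0.57
Leu,CUG,1.892,2.53,2.28,2.73
Ile,AUU,0.864,1.03,1.00,0.74
Ile,AUC,1.167,1.52,1.59,1.86
Ile,AUA,0.967,0.44,0.40,0.40
Val,GUU,0.843,0.69,1.05,0.88
Val,GUC,1.099,1.00,1.09,1.30
Val,GUA,0.387,0.42,0.60,0.51
Val,GUG,1.668,1.90,1.26,1.31
Ser,UCU,0.854,1.11,0.67,0.54
Ser,UCC,0.985,1.39,1.20,1.40
Ser,UCA,1.515,0.84,0.68,0.48
Ser,UCG,0.420,0.33,1.41,1.70
Ser,AGU,0.997,0.84,0.93,0.79
Ser,AGC,1.228,1.50,1.11,1.08
Pro,CCU,0.671,1.12,0.67,0.35
Pro,CCC,1.129,1.35,0.83,1.13
Pro,CCA,1.809,1.07,1.20,1.07
Pro,CCG,0.391,0.46,1.30,1.44
Thr,ACU,0.980,0.94,0.80,0.64
Thr,ACC,1.133,1.52,1.48,1.79
Thr,ACA,1.478,1.07,0.70,0.58
Thr,ACG,0.409,0.46,1.01,0.99
Ala,GCU,1.132,1.09,1.09,0.99
Ala,GCC,1.290,1.64,1.48,1.81
Ala,GCA,1.125,0.85,0.75,0.59
Ala,GCG,0.453,0.42,0.69,0.62
Tyr,UAU,0.761,0.84,0.64,0.55
Tyr,UAC,1.239,1.16,1.36,1.45
His,CAU,0.863,0.81,0.84,0.75
His,CAC,1.137,1.19,1.16,1.25
Gln,CAA,1.112,0.51,0.81,0.60
Gln,CAG,0.888,1.49,1.19,1.40
Asn,AAU,0.692,0.89,0.79,0.64
Asn,AAC,1.308,1.11,1.21,1.36
Lys,AAA,0.854,0.82,0.79,0.58
Lys,AAG,1.146,1.18,1.21,1.42
Asp,GAU,0.903,0.89,1.12,0.96
Asp,GAC,1.097,1.11,0.88,1.04
Glu,GAA,0.930,0.81,1.15,1.11
Glu,GAG,1.070,1.19,0.85,0.89
Cys,UGU,0.941,0.86,0.83,0.69
Cys,UGC,1.060,1.14,1.17,1.31
Arg,CGU,0.450,0.51,1.36,1.5
Arg,CGC,0.600,1.20,1.25,1.32
Arg,CGA,0.253,0.63,1.17,0.97
Arg,CGG,0.559,1.20,1.05,1.22
Arg,AGA,2.443,1.20,0.64,0.58
Arg,AGG,1.692,1.26,0.53,0.41
Gly,GGU,0.529,0.64,1.10,1.24
Gly,GGC,0.672,1.40,1.04,1.07
Gly,GGA,1.793,0.98,1.49,1.21
Gly,GGG,1.006,0.98,0.37,0.47
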