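# normalized viability; DMSO row/column first
# drug_a=osimertinib drug_b=trametinib
b\a,0,1.17187e-09,4.6875e-09,1.875e-08,7.5e-08,3e-07
0,1,0.947292,0.797318,0.514031,0.22124,0.0552681
3.90625e-10,0.912795,0.867966,0.774683,0.509889,0.210123,0.0578532
1.5625e-09,0.839889,0.75385,0.667663,0.424136,0.177914,0.0559128
6.25e-09,0.481563,0.441835,0.399367,0.225469,0.116419,0.023582
2.5e-08,0.175479,0.180955,0.171669,0.11833,0.0499015,0.00769287
1e-07,0.0767961,0.0576542,0.0490407,0.0183979,0.0076234,0
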