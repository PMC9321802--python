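# provenance=italian_wet_amd_v1: eight wet-AMD risk variants validated in the Italian population; per-genotype odds ratios normalized to a population-average risk of 1
rs_id,gene,ref,alt,genotype,or_point,ci_low,ci_high
rs1061170,CFH,T,C,TT,0.19,0.14,0.25
rs1061170,CFH,T,C,CT,2.19,1.76,2.72
rs1061170,CFH,T,C,CC,5.16,3.9,6.82
rs10490924,ARMS2,G,T,GG,0.12,0.08,0.17
rs10490924,ARMS2,G,T,GT,2.38,1.95,2.9
rs10490924,ARMS2,G,T,TT,8.3,5.73,12.04
rs2227306,IL8,C,T,CC,0.53,0.39,0.72
rs2227306,IL8,C,T,CT,1.32,1.08,1.59
rs2227306,IL8,C,T,TT,1.87,1.38,2.53
rs5749482,TIMP3,C,G,CC,0.63,0.31,1.29
rs5749482,TIMP3,C,G,CG,1.0,0.45,1.91
rs5749482,TIMP3,C,G,GG,1.56,0.77,3.16
rs8135665,SLC16A8,C,T,CC,0.44,0.28,0.69
rs8135665,SLC16A8,C,T,CT,1.59,1.3,1.95
rs8135665,SLC16A8,C,T,TT,2.25,1.44,3.51
rs8017304,RAD51B,A,G,AA,0.69,0.52,0.91
rs8017304,RAD51B,A,G,AG,1.15,0.94,1.4
rs8017304,RAD51B,A,G,GG,1.44,1.1,1.88
rs943080,VEGFA,C,T,CC,0.59,0.45,0.77
rs943080,VEGFA,C,T,CT,1.23,0.97,1.55
rs943080,VEGFA,C,T,TT,1.69,1.29,2.19
rs13081855,COL8A1,G,T,GG,0.16,0.04,0.55
rs13081855,COL8A1,G,T,GT,1.85,1.43,2.39
rs13081855,COL8A1,G,T,TT,6.19,1.78,21.49
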