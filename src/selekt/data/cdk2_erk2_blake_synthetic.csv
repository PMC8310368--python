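# Synthetic stand-in for the CDK2/ERK2 congeneric-series affinity table
# (Blake-style series, reference compound 6). Per-ligand values are
# constructed, not transcribed; they are calibrated so the selectivity
# summary S(ERK2-CDK2) reproduces the published series statistics
# (mean -1.74, sd 0.56, range 2.2 kcal/mol). IC50 ~ Ki under the
# Km(ATP) >> [S0] assumption; compound 9 (predicted charged) is flagged
# exclude_from_analysis and kept only for map cycle closure.
ligand_id,target_id,quantity,value,unit,km_atp_uM,s0_atp_uM,temperature_K,exclude_from_analysis
6,CDK2,IC50,357.3,nM,,,300,False
6,ERK2,IC50,127.5,nM,,,300,False
1,CDK2,IC50,617.8,nM,,,300,False
1,ERK2,IC50,63.4,nM,,,300,False
2,CDK2,IC50,483.8,nM,,,300,False
2,ERK2,IC50,39.37,nM,,,300,False
3,CDK2,IC50,159.7,nM,,,300,False
3,ERK2,IC50,12.51,nM,,,300,False
4,CDK2,IC50,185.8,nM,,,300,False
4,ERK2,IC50,13.58,nM,,,300,False
5,CDK2,IC50,589.1,nM,,,300,False
5,ERK2,IC50,42.21,nM,,,300,False
7,CDK2,IC50,102.6,nM,,,300,False
7,ERK2,IC50,3.587,nM,,,300,False
8,CDK2,IC50,530.2,nM,,,300,False
8,ERK2,IC50,18.03,nM,,,300,False
10,CDK2,IC50,505.0,nM,,,300,False
10,ERK2,IC50,15.17,nM,,,300,False
11,CDK2,IC50,260.4,nM,,,300,False
11,ERK2,IC50,7.628,nM,,,300,False
12,CDK2,IC50,186.8,nM,,,300,False
12,ERK2,IC50,1.664,nM,,,300,False
9,CDK2,IC50,2500.0,nM,,,300,True
9,ERK2,IC50,410.0,nM,,,300,True
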