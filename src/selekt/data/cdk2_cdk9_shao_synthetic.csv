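# Synthetic stand-in for the CDK2/CDK9 congeneric-series affinity table
# (Shao-style series, reference ligand 1a). Per-ligand values are
# constructed, not transcribed; they are calibrated so the selectivity
# summary S(CDK9-CDK2) reproduces the published series statistics
# (mean -0.65, sd 0.88, range 2.8 kcal/mol). Ki values already include
# the per-kinase Cheng-Prusoff correction, as in the source assay.
ligand_id,target_id,quantity,value,unit,km_atp_uM,s0_atp_uM,temperature_K,exclude_from_analysis
1a,CDK2,Ki,280.1,nM,,,300,False
1a,CDK9,Ki,1266.0,nM,,,300,False
12a,CDK2,Ki,281.5,nM,,,300,False
12a,CDK9,Ki,547.3,nM,,,300,False
12b,CDK2,Ki,172.3,nM,,,300,False
12b,CDK9,Ki,313.1,nM,,,300,False
12c,CDK2,Ki,117.2,nM,,,300,False
12c,CDK9,Ki,76.2,nM,,,300,False
12d,CDK2,Ki,79.45,nM,,,300,False
12d,CDK9,Ki,48.23,nM,,,300,False
12e,CDK2,Ki,138.1,nM,,,300,False
12e,CDK9,Ki,59.47,nM,,,300,False
12f,CDK2,Ki,144.0,nM,,,300,False
12f,CDK9,Ki,19.07,nM,,,300,False
12g,CDK2,Ki,78.31,nM,,,300,False
12g,CDK9,Ki,9.758,nM,,,300,False
12h,CDK2,Ki,78.77,nM,,,300,False
12h,CDK9,Ki,9.776,nM,,,300,False
12i,CDK2,Ki,387.9,nM,,,300,False
12i,CDK9,Ki,39.61,nM,,,300,False
12j,CDK2,Ki,216.8,nM,,,300,False
12j,CDK9,Ki,19.24,nM,,,300,False
12k,CDK2,Ki,107.6,nM,,,300,False
12k,CDK9,Ki,4.437,nM,,,300,False
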