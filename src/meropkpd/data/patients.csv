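patient_id,subgroup,age_years,sex,bmi_kg_m2,apache2,sofa,crcl_ml_min,map_mmhg,wbc_10e9_L,pct_ug_L,pct_censored,pathogens
1,crcl_normal,23,male,17.9,11,3,160.9,60,14.8,2.6,false,Candida albicans
2,crcl_normal,75,male,23.6,26,13,54.2,60,20.1,100,true,Pseudomonas aeruginosa (MIC=4); Klebsiella pneumoniae (MIC<=0.25); Streptococcus viridis
3,crcl_normal,73,female,25.4,31,11,91.4,44,14.7,14,false,Enterococcus faecium (MIC=8); E. coli (MIC<=0.25)
4,crcl_normal,41,male,25.8,17,5,87.1,54,15.8,3.2,false,E. coli (MIC<=0.25)
5,crcl_normal,70,male,27.1,25,11,55.0,58,18.6,100,true,Klebsiella pneumoniae (MIC=2)
6,crcl_normal,42,male,21.2,16,4,90.3,42,13.0,0.23,false,E. coli (MIC<=0.25)
7,crcl_normal,31,male,26.2,18,6,168.4,47,6.8,13,false,NR
8,crcl_normal,57,female,19.8,16,9,125.5,64,14.9,28.7,false,Klebsiella pneumoniae (MIC<=0.25)
9,crcl_normal,49,female,24.5,24,8,109.1,60,17.4,5.5,false,NR
10,crcl_abnormal,52,male,26.0,26,11,25.4,62,30.2,37,false,E. coli (MIC<=0.25); Klebsiella pneumoniae (MIC<=0.25)
11,crcl_abnormal,71,female,25.6,25,8,47.0,53,13.1,6.7,false,E. coli (MIC<=0.25)
12,crcl_abnormal,65,female,27.4,17,9,42.7,60,18.9,0.8,false,E. coli (MIC=2); Enterobacter cloacae (MIC<=0.25)
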