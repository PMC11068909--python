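patient_id,auc_mg_h_L,cl_L_h,vd_L,cmax_mg_L,tmax_h,t_half_h
1,81.5,10.6,32.9,43.2,0.25,3.5
2,141.1,6.0,20.9,64.3,0.25,2.7
3,134.3,7.1,15.1,69.8,0.5,1.8
4,137.6,6.4,20.1,53.1,0.5,2.4
5,115.2,7.8,22.4,64.1,0.25,2.4
6,116.3,7.9,21.6,50.7,0.5,2.2
7,97.1,9.6,24.7,54.1,0.25,2.1
8,168.9,4.9,19.0,62.6,0.25,2.9
9,96.3,9.1,27.0,66.8,0.25,3.0
10,144.3,5.6,23.9,62.0,0.25,3.3
11,225.0,3.9,13.0,77.8,0.25,2.3
12,228.8,3.6,14.8,68.5,0.5,3.0
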