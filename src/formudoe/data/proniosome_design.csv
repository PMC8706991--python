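run_id,finasteride_mM,total_lipid_mM,cholesterol_pct,is_center,size_nm,size_sd,ee_pct,ee_sd,dl_pct,dl_sd
1,6.19,20.00,40.00,0,255.80,4.09,90.31,1.35,21.85,1.52
2,1.50,30.00,50.00,0,263.40,5.55,88.21,1.42,4.22,1.49
3,0.31,20.00,40.00,0,258.20,3.77,79.77,2.31,1.20,1.34
4,3.25,20.00,40.00,1,290.60,3.05,93.68,1.65,13.21,1.32
5,1.50,10.00,50.00,0,220.20,1.99,72.57,2.01,9.81,1.05
6,3.25,20.00,40.00,1,290.60,3.05,93.68,1.65,13.21,1.32
7,3.25,20.00,40.00,1,292.20,2.59,94.57,3.74,13.32,1.54
8,3.25,20.00,40.00,1,295.00,3.74,94.05,1.66,13.25,1.51
9,5.00,30.00,50.00,0,300.20,5.40,94.73,2.13,13.63,1.31
10,3.25,20.00,40.00,1,293.00,3.67,93.35,1.51,13.17,1.26
11,3.25,20.00,56.82,0,285.60,4.72,91.26,1.12,12.91,1.64
12,3.25,20.00,40.00,1,292.60,2.61,93.60,1.33,13.20,1.33
13,1.50,30.00,30.00,0,335.60,8.20,92.01,2.65,4.39,2.33
14,3.25,3.18,40.00,0,242.80,3.70,71.95,1.24,43.05,1.61
15,5.00,10.00,50.00,0,223.00,1.81,89.36,1.31,30.88,1.23
16,5.00,10.00,30.00,0,261.20,4.27,84.77,3.01,29.77,1.84
17,3.25,36.82,40.00,0,329.40,6.69,91.61,2.34,7.48,1.31
18,5.00,30.00,30.00,0,332.40,2.97,83.24,2.61,12.18,1.30
19,3.25,20.00,23.18,0,346.00,1.86,95.44,1.11,13.42,1.67
20,1.50,10.00,30.00,0,261.60,5.22,89.45,1.32,11.83,2.21
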