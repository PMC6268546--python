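index,compound,role,R_pct,R_sd_pct,perm_pct,perm_sd_pct,log_pe,log_pe_sd,below_detection_R
1,FA-21-MP,ester,34.1,3.5,23.1,1.4,-4.64,0.17,False
2,FA-21-EP,ester,45.8,4.1,22.2,1.6,-4.52,0.19,False
3,FA-21-PhP,ester,71.9,2.8,1.3,0.6,-5.68,0.15,False
4,FA-21-MB,ester,47.2,3.4,18.0,1.3,-4.65,0.12,False
5,FA-21-EB,ester,72.8,2.6,7.2,0.9,-4.82,0.10,False
6,DEX-21-MP,ester,0.5,,23.8,1.5,-4.88,0.17,True
7,DEX-21-EP,ester,0.5,,31.6,0.6,-4.70,0.11,True
8,DEX-21-PhP,ester,86.5,4.2,4.1,1.1,-4.74,0.13,False
9,DEX-21-MB,ester,0.5,,37.4,1.5,-4.58,0.15,True
10,DEX-21-EB,ester,11.3,3.5,33.4,1.2,-4.58,0.13,False
11,TA-21-MP,ester,13.5,4.1,38.1,1.6,-4.45,0.16,False
12,TA-21-EP,ester,32.4,1.7,23.0,1.8,-4.66,0.15,False
13,TA-21-PhP,ester,51.1,3.8,27.1,1.4,-4.07,0.14,False
14,TA-21-MB,ester,39.3,4.1,16.9,2.0,-4.85,0.23,False
15,TA-21-EB,ester,70.1,3.4,7.3,1.6,-4.87,0.21,False
16,H-21-MP,ester,2.6,1.9,14.9,1.8,-5.11,0.25,False
17,H-21-EP,ester,17.2,2.2,16.3,1.9,-4.99,0.19,False
18,H-21-PhP,ester,72.2,3.1,10.6,1.2,-4.58,0.15,False
19,H-21-MB,ester,9.6,3.2,18.5,1.9,-4.97,0.28,False
20,H-21-EB,ester,38.6,1.8,17.6,1.4,-4.77,0.17,False
21,FA,standard,0.5,,6.7,1.2,-5.26,0.15,True
22,DEX,standard,4.2,2.0,1.3,0.8,-5.99,0.10,False
23,TA,standard,4.7,2.3,10.8,1.5,-5.01,0.17,False
24,H,standard,1.5,0.9,0.8,0.5,-6.23,0.09,False
25,H-21-Ac,standard,0.5,,10.0,1.7,-5.07,0.19,True
26,MF,standard,81.0,2.9,7.7,1.5,-4.10,0.15,False
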