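dose_gy,int_60x,sd_60x,rsd_60x,int_40x,sd_40x,rsd_40x,int_commercial,sd_commercial,rsd_commercial
0,1.65,0.18,11.2,1.44,0.14,9.6,1.52,0.13,8.8
0,1.66,0.18,11.1,1.39,0.13,9.6,1.20,0.13,11.2
0.2,3.50,0.39,11.1,3.41,0.32,9.5,1.72,0.17,10.1
0.3,4.33,0.53,12.3,4.25,0.47,11.0,3.85,0.22,5.7
0.4,4.65,0.46,10.0,5.14,0.60,11.7,2.54,0.12,4.9
0.5,6.40,0.68,10.6,6.00,0.64,10.7,3.18,0.22,7.0
0.6,7.04,0.81,11.5,7.34,0.75,10.3,2.90,0.19,6.5
0.7,7.21,0.78,10.9,7.24,0.68,9.4,3.44,0.32,9.3
0.8,8.5,1.0,11.9,8.2,0.8,9.2,3.6,0.3,8.7
0.9,9.2,1.1,12.5,8.71,0.71,8.1,3.9,0.3,8.3
1.0,9.8,1.1,11.5,9.0,1.0,10.8,4.7,0.2,4.9
1.0,8.8,1.1,12.5,9.2,1.2,12.9,3.6,0.2,6.8
1.2,11.9,1.3,10.8,11.2,1.0,9.3,6.1,0.5,8.5
1.4,12.1,1.5,12.0,13.1,1.2,9.3,6.1,0.3,5.1
1.6,12.9,1.8,14.1,13.9,1.7,12.2,6.1,0.5,7.7
1.8,16.0,1.7,10.7,15.6,1.5,9.6,7.5,0.5,6.1
2.0,15.5,1.8,11.4,17.1,1.5,8.8,8.3,0.5,5.5
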