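locus,chromosome_label,missing_pct,d_AR,d_RAR,d_rarefied,d_Nei,d_PIC,d_SWI
barc019,3A,0.0,16,8,7.9,0.74,0.71,1.71
barc021,7A,2.7,16,6,8.4,0.58,0.57,1.46
barc029,7A,1.7,12,6,5.8,0.61,0.57,1.28
barc032,5B,0.9,16,5,9.9,0.83,0.81,2.06
barc096,6D,0.2,16,12,5.1,0.53,0.47,1.07
barc097,7BD5B,16.9,11,6,5.8,0.74,0.70,1.52
barc107,6A,0.9,14,8,6.2,0.50,0.46,1.12
barc110,5D,0.3,29,14,14.9,0.93,0.92,2.75
barc127,6B,0.4,19,12,8.2,0.83,0.81,1.97
barc134,6B,11.2,20,12,9.0,0.80,0.78,1.93
barc164,3B,0.1,29,16,13.3,0.86,0.85,2.42
barc172,7BD5B,0.0,11,3,6.8,0.77,0.74,1.67
barc240,1ABD5B,0.1,33,18,13.1,0.85,0.83,2.37
cfd079.a,3ABD,8.4,26,9,14.5,0.91,0.90,2.65
cfd079.b,3ABD,14.0,13,8,6.5,0.74,0.70,1.59
gdm111,1D,7.8,13,5,7.3,0.75,0.71,1.64
gdm129,4D,0.0,8,5,3.4,0.22,0.21,0.49
gwm003,3D,0.0,16,9,7.2,0.69,0.66,1.56
gwm018,1B,0.6,15,7,7.8,0.74,0.71,1.69
gwm030.a,2D3A,23.2,16,8,9.0,0.79,0.77,1.91
gwm030.b,2D3A,10.4,28,9,16.9,0.93,0.93,2.88
gwm046,7B,1.6,28,10,15.1,0.91,0.91,2.71
gwm095,2A,0.0,14,7,7.7,0.81,0.79,1.86
gwm155,1D3A,0.5,24,13,10.1,0.80,0.78,2.01
gwm190,5D,0.6,22,12,9.9,0.84,0.83,2.12
gwm213,5B,1.5,46,19,23.0,0.96,0.95,3.38
gwm219,6B,0.0,30,11,16.0,0.91,0.91,2.76
gwm291,5A,13.0,29,12,15.0,0.87,0.86,2.56
gwm312,2A,0.1,43,25,17.3,0.89,0.88,2.80
gwm337,1D,3.3,25,11,12.6,0.88,0.87,2.43
gwm357,1A,0.1,11,4,6.1,0.73,0.69,1.53
gwm437,7D,0.0,26,8,16.3,0.93,0.93,2.83
gwm456,3D,0.1,18,7,10.1,0.84,0.82,2.10
gwm526.a,2B,3.7,7,3,4.2,0.62,0.58,1.18
gwm526.b,2B,3.5,15,6,8.5,0.77,0.74,1.80
gwm539,2D,0.4,61,34,23.5,0.96,0.96,3.45
gwm570,6A,0.0,26,14,12.7,0.89,0.88,2.45
gwm608.a,2D4D6B,21.4,6,0,6.0,0.80,0.77,1.70
gwm608.c,2D4D6B,0.7,20,9,11.3,0.89,0.88,2.38
psp3100,1B,0.6,54,36,17.6,0.92,0.92,2.95
wmc093,1AD,1.1,9,7,2.7,0.51,0.39,0.78
wmc105,6B,4.1,40,20,18.5,0.91,0.90,2.90
wmc110,5A,22.4,3,0,2.7,0.34,0.29,0.59
wmc154,2B,0.6,38,28,11.5,0.78,0.76,2.11
wmc168,7A,12.3,34,14,15.3,0.80,0.79,2.40
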