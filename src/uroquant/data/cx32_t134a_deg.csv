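gene,q,log2fc
CLCA4,0.008,1.96
MGAM,0.014,1.82
ID3,0.016,1.73
COL12A1,0.009,1.68
CCDC80,0.013,1.66
ID2,0.001,1.66
ALDH1A1,0.007,1.65
GKN1,0.018,1.65
CYP24A1,0.001,1.54
NDUFA4L2,0.009,1.48
ENPP1,0.015,1.46
OLR1,0.004,1.39
SELENOP,0.004,1.37
MATN2,0.012,1.36
SERPING1,0.025,1.35
ACKR3,0.001,1.33
HEG1,0.008,1.33
SCUBE2,0.005,1.32
CFI,0.020,1.31
GKN2,0.029,1.29
VCAN,0.002,1.26
CD200R1,0.002,1.21
CLCA2,0.049,1.21
VWA5B1,0.041,1.21
IGFBP2,0.017,1.20
ATOH8,0.003,1.18
BMP2,0.023,1.18
LOX,0.036,1.15
IFITM10,0.024,1.14
CD86,0.002,1.14
CAV1,0.004,1.12
PPFIA4,0.003,1.11
SUGCT,0.025,1.10
LINC01835,0.034,1.09
PDLIM2,0.012,1.09
ASPA,0.012,1.08
CDH10,0.001,1.08
S1PR3,0.002,1.08
NPIPA7,0.041,1.07
GLIPR1,0.004,1.07
S100A3,0.013,1.07
PALM,0.012,1.07
ITGB3,0.034,1.07
ANOS1,0.019,1.06
KLK13,0.015,1.03
LGALS1,0.004,1.02
CHL1,0.012,1.02
EPHA4,0.006,1.02
COL17A1,0.002,1.01
TRAV30,0.050,1.00
BPIFA2,0.004,-1.08
CEACAM6,0.013,-1.11
ITGB8,0.005,-1.27
PSG6,0.003,-1.39
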