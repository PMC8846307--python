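sample,group,GAPDH,RPL4,EEF1A1,RPS9,HPRT1,UXT,HMBS,B2M,RPS15,ACTB
LAC1,cold_arid,22.17,21.56,18.81,22.40,30.18,26.07,29.44,19.36,19.51,24.35
LAC2,cold_arid,21.87,20.06,17.32,20.15,28.38,23.86,27.99,18.20,19.79,22.88
LAC3,cold_arid,22.08,19.67,16.90,19.98,27.95,24.18,27.63,18.72,19.55,23.52
LAC4,cold_arid,22.30,20.15,17.26,19.87,28.14,24.55,27.64,18.57,19.57,24.66
LAC5,cold_arid,22.53,19.61,17.09,20.04,28.87,24.68,27.59,18.75,19.21,22.64
LAC6,cold_arid,22.07,19.75,17.23,20.41,29.69,24.51,27.79,17.74,19.45,24.90
HFX1,cold_arid,21.52,19.35,16.90,19.73,27.46,24.30,27.80,17.61,18.80,21.33
HFX2,cold_arid,21.16,19.40,17.21,20.13,27.31,24.83,27.94,17.18,19.09,20.65
HFX3,cold_arid,21.64,19.71,17.12,20.07,27.71,24.41,27.77,17.82,19.12,21.16
HFX4,cold_arid,21.66,19.76,17.00,20.13,28.55,23.46,27.81,17.66,18.93,21.71
HFX5,cold_arid,21.90,19.78,17.48,20.08,27.83,26.76,27.92,17.81,19.38,22.36
JYC1,cold_arid,21.71,19.39,17.25,20.13,28.40,25.27,27.77,17.64,19.16,21.82
JYC2,cold_arid,21.41,20.10,17.79,20.59,27.80,26.42,27.87,17.72,19.74,22.03
JYC3,cold_arid,21.44,19.34,17.21,20.53,27.43,26.31,26.89,17.82,19.43,27.44
JYC4,cold_arid,22.24,20.58,18.34,21.14,28.26,29.62,28.56,18.85,20.24,22.93
SAC1,hot_arid,21.60,20.38,18.34,20.40,24.43,27.86,28.21,18.09,19.83,21.60
SAC2,hot_arid,21.87,20.18,18.36,20.63,24.95,23.99,27.97,18.04,19.39,21.09
SAC3,hot_arid,22.96,20.04,18.70,20.73,24.09,24.36,28.57,18.91,19.72,23.71
SAC4,hot_arid,22.49,20.65,18.78,20.84,24.64,24.63,28.68,18.29,20.11,22.49
SAC5,hot_arid,22.23,20.80,19.10,21.00,24.91,24.90,28.90,18.71,20.49,22.04
KFC1,hot_arid,22.07,19.84,18.18,20.73,24.58,24.25,27.81,18.10,19.88,21.79
KFC2,hot_arid,21.63,19.73,19.32,20.77,24.44,24.17,27.51,17.75,19.63,21.18
KFC3,hot_arid,21.45,19.24,17.66,19.89,23.60,24.23,27.31,17.73,18.97,21.20
KFC4,hot_arid,21.39,18.73,17.51,19.92,23.71,23.81,26.99,17.57,18.39,21.41
KFC5,hot_arid,21.74,19.65,17.94,20.65,24.40,24.30,28.04,17.95,19.54,21.51
HFC1,hot_arid,19.47,17.07,15.49,18.01,21.51,21.83,26.62,15.69,17.02,18.73
HFC2,hot_arid,22.44,20.56,19.27,21.35,25.41,25.16,28.58,20.29,20.32,22.72
HFC3,hot_arid,19.08,17.03,15.36,17.81,21.59,21.53,24.87,17.95,16.73,18.12
HFC4,hot_arid,20.76,18.38,16.84,21.11,24.78,24.53,29.61,20.04,20.43,24.27
HFC5,hot_arid,21.95,19.90,18.26,20.73,24.61,24.25,27.72,18.96,19.21,21.78
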