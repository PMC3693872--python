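cell_line,compound1,compound2,ic50_uM,m,ci,r2
A204,SAHA,,24.72,0.6,,0.72
A204,M344,,128.76,0.57,,0.67
A204,TSA,,1.83,0.43,,0.87
A204,Tam,,2.67,0.5,,0.86
A204,Fen,,1.87,0.4,,0.84
A204,SAHA,Tam,0.97,0.36,0.07,0.75
A204,SAHA,Fen,1.25,0.48,0.1,0.72
A204,M344,Tam,0.97,0.48,0.19,0.56
A204,M344,Fen,0.28,0.24,0.01,0.88
A204,TSA,Tam,0.16,0.2,0.08,0.77
A204,TSA,Fen,0.1,0.24,0.05,0.73
G401,SAHA,,31.82,0.44,,0.87
G401,Tam,,3.13,0.53,,0.89
G401,Fen,,3.37,0.54,,0.85
G401,SAHA,Tam,1.42,0.3,0.06,0.9
G401,SAHA,Fen,1.65,0.54,0.09,0.91
BT16,SAHA,,8.39,0.64,,0.93
BT16,Tam,,2.09,0.75,,0.9
BT16,Fen,,2.74,0.5,,0.91
BT16,SAHA,Tam,0.11,0.44,0.02,0.87
BT16,SAHA,Fen,0.43,0.52,0.06,0.86
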