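cell_line,compound1,compound2,ic50_uM,m,ci,r2
A204,SAHA,,24.72,0.6,,0.72
A204,DOXO,,6.48,0.37,,0.72
A204,DOXO,SAHA,0.16,0.22,0.02,0.76
G401,SAHA,,31.82,0.44,,0.87
G401,DOXO,,0.67,0.38,,0.77
G401,DOXO,SAHA,0.03,0.17,0.03,0.85
BT16,SAHA,,8.39,0.64,,0.93
BT16,DOXO,,0.13,0.18,,0.83
BT16,DOXO,SAHA,0.003,0.2,0.02,0.81
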