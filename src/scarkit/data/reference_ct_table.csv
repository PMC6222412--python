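label,quantity_ng,ct
C_militaris,15,7.55
C_militaris,1.5,10.30
C_militaris,0.15,13.65
C_militaris,0.015,17.27
C_militaris,0.0015,20.75
C_pruinosa,15,11.27
C_pruinosa,1.5,14.02
C_pruinosa,0.15,17.60
C_pruinosa,0.015,21.28
C_pruinosa,0.0015,24.46
I_cicadae,15,14.72
I_cicadae,1.5,17.97
I_cicadae,0.15,21.47
I_cicadae,0.015,24.76
I_cicadae,0.0015,28.19
I_tenuipes,15,13.89
I_tenuipes,1.5,14.62
I_tenuipes,0.15,17.50
I_tenuipes,0.015,20.88
I_tenuipes,0.0015,24.55
O_sinensis,15,8.31
O_sinensis,1.5,11.66
O_sinensis,0.15,15.06
O_sinensis,0.015,18.68
O_sinensis,0.0015,21.98
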