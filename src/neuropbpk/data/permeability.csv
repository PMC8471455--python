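# Transwell apparent permeabilities (units of 1e-6 cm/s, as conventionally
# tabulated) and brain-homogenate unbound fraction, per drug x cell line.
drug,cell_line,papp_ab_1e-6_cm_per_s,papp_ba_1e-6_cm_per_s,fu_brain
amitriptyline,MDCK,74.77,178.48,0.037
amitriptyline,MDCK-MDR1,17.95,16.91,0.104
amitriptyline,hCMEC,124.24,66.21,0.252
caffeine,MDCK,26.10,35.31,0.857
caffeine,MDCK-MDR1,33.57,30.59,0.613
caffeine,hCMEC,63.93,194.70,0.095
carbamazepine,MDCK,114.64,78.66,0.673
carbamazepine,MDCK-MDR1,142.96,75.64,0.238
carbamazepine,hCMEC,70.14,51.93,0.386
fleroxacin,MDCK,88.48,63.44,0.471
fleroxacin,MDCK-MDR1,67.40,42.57,0.813
fleroxacin,hCMEC,29.96,25.73,0.743
pefloxacin,MDCK,41.21,37.49,0.910
pefloxacin,MDCK-MDR1,30.82,35.39,0.931
pefloxacin,hCMEC,24.95,33.14,0.642
zolpidem,MDCK,21.32,36.48,0.971
zolpidem,MDCK-MDR1,8.92,33.43,0.881
zolpidem,hCMEC,106.16,80.76,0.408
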