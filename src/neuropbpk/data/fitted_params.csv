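# Per-drug PK parameters (V_d, k_el, k_a) and per-drug-per-cell-line scaling
# factors (SC1, SC2, SC3) after fitting to rat plasma/brain profiles. Long
# format: PK columns repeat across the three cell-line rows of each drug.
drug,cell_line,vd_cm3,kel_per_s,ka_per_s,sc1,sc2,sc3
amitriptyline,MDCK,14632.6,1.17e-4,5.86e-3,220.59,224.82,0.05
amitriptyline,MDCK-MDR1,14632.6,1.17e-4,5.86e-3,920.39,2377.06,0.02
amitriptyline,hCMEC,14632.6,1.17e-4,5.86e-3,132.89,606.69,0.01
caffeine,MDCK,273.6,3.55e-5,,3.85,1.00,0.22
caffeine,MDCK-MDR1,273.6,3.55e-5,,2.85,1.00,0.31
caffeine,hCMEC,273.6,3.55e-5,,4.09,1.00,2.15
carbamazepine,MDCK,827.0,5.39e-5,2.15e-4,25.71,81.01,1.16
carbamazepine,MDCK-MDR1,827.0,5.39e-5,2.15e-4,95.00,391.22,0.71
carbamazepine,hCMEC,827.0,5.39e-5,2.15e-4,193.66,569.98,0.44
fleroxacin,MDCK,327.3,2.69e-5,,3.18,12.96,1.07
fleroxacin,MDCK-MDR1,327.3,2.69e-5,,1.59,6.43,0.68
fleroxacin,hCMEC,327.3,2.69e-5,,3.58,10.65,0.74
pefloxacin,MDCK,524.3,6.75e-5,,4.88,13.32,0.55
pefloxacin,MDCK-MDR1,524.3,6.75e-5,,6.15,13.19,0.56
pefloxacin,hCMEC,524.3,6.75e-5,,7.59,14.09,0.81
zolpidem,MDCK,185.9,5.12e-4,,16.53,26.79,0.27
zolpidem,MDCK-MDR1,185.9,5.12e-4,,20.59,14.51,0.30
zolpidem,hCMEC,185.9,5.12e-4,,10.26,38.70,0.65
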