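# Systemic PK and dosing description per drug (rat studies; literature initial
# estimates). Units: V_d cm^3, k_el and k_a 1/s, dose ng, k_0 ng/s, weight g.
# Empty cells = parameter absent for that drug (drives dosing-mode inference).
drug,fu_plasma,vd_cm3,kel_per_s,ka_per_s,dose_ng,k0_ng_per_s,rat_weight_g
amitriptyline,0.090,4000,7.70e-5,1.54e-4,5000000,,250
caffeine,0.917,180,3.55e-5,,,833.333,300
carbamazepine,0.385,1490.5,4.50e-5,8.99e-5,3600000,,300
fleroxacin,0.793,427.5,7.13e-5,,1114350,83.125,285
pefloxacin,0.860,361.1,5.83e-5,,3676500,214.542,285
zolpidem,0.267,304,1.56e-4,,499700,,190
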