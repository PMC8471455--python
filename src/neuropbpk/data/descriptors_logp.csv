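# Experimental octanol-water partition coefficients (logP) for the six model
# drugs, from the standard public compilations (PubChem / Hansch et al.).
drug,logp
amitriptyline,4.92
caffeine,-0.07
carbamazepine,2.45
fleroxacin,0.24
pefloxacin,0.27
zolpidem,2.42
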