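pfam_acc	role	note
PF01618	motor_pentamer	MotA/ExbB/TolQ proton channel
PF02472	motor_dimer	MotB/ExbD/TolR peptidoglycan-binding subunit
PF06519	transducer	TolA-TonB force transducer
PF03544	transducer	TonB C-terminal domain (shared TolA/TonB CTD)
PF13103	transducer	TolA-TonB force transducer
PF16031	transducer	TonB polyproline region
PF07676	tolB_propeller	TolB six-bladed beta-propeller
PF04052	tolB_nterm	TolB N-terminal Rossmann-like domain
PF00691	pal	OmpA-like peptidoglycan-binding lipoprotein
PF16331	cpoB_tpr	CpoB tetratricopeptide repeat
PF13432	cpoB_tpr	CpoB tetratricopeptide repeat
PF13174	cpoB_tpr	CpoB tetratricopeptide repeat
PF03061	ybgC	acyl-thioesterase
PF00593	tbdt_barrel	TonB-dependent receptor beta-barrel
PF07715	tbdt_plug	TonB-dependent receptor plug domain
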