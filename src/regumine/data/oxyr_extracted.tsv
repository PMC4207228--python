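tf	target	resolved_effect	status	support_pos	support_neg	support_nondir	support_noeffect	gcs
OxyR	fhuF	negative	supported	0	1	0	0	Hydrogen peroxide treatment
OxyR	flu	dual	conflicting	1	65	3	0	Hydrogen peroxide treatment
OxyR	gor	positive	supported	1	0	0	0	Hydrogen peroxide treatment
OxyR	grxA	positive	supported	1	0	0	0	Hydrogen peroxide treatment
OxyR	katG	positive	supported	1	0	0	0	Hydrogen peroxide treatment
OxyR	mntH	positive	supported	1	0	0	0	Hydrogen peroxide treatment
OxyR	oxyS	dual	conflicting	18	1	0	0	Hydrogen peroxide treatment
OxyR	sufABCDSE	positive	supported	1	0	0	0	Hydrogen peroxide treatment
OxyR	trxC	positive	supported	1	0	0	0	Hydrogen peroxide treatment
OxyR	uof-fur	positive	supported	1	0	0	0	Hydrogen peroxide treatment
OxyR	ychF	negative	supported	0	1	0	0	Hydrogen peroxide treatment
OxyR	ahpCF	positive	supported	1	0	0	0	Hydrogen peroxide treatment, ascorbate treatment
OxyR	dps	positive	supported	1	0	0	0	Hydrogen peroxide treatment, exponential phase, stationary phase
OxyR	gntP	negative	supported	0	1	0	0	
OxyR	hcp-hcr	positive	supported	1	0	0	0	
OxyR	uxuAB	negative	supported	0	1	0	0	
OxyR	ybjC-nfsA-rimK-ybjN	negative	supported	0	1	0	0	
OxyR	yhjA	positive	supported	1	0	0	0	
OxyR	dsbG	positive	supported	1	0	0	0	Oxidative stress
OxyR	hemH	positive	supported	1	0	0	0	Oxidative stress
OxyR	oxyR	negative	supported	0	1	0	0	Oxidative stress, reducing conditions
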