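tf	target	effect	gcs
OxyR	fhuF	Repressor	Hydrogen peroxide treatment
OxyR	flu	Repressor	Hydrogen peroxide treatment
OxyR	gor	Activator	Hydrogen peroxide treatment
OxyR	grxA	Activator	Hydrogen peroxide treatment
OxyR	katG	Activator	Hydrogen peroxide treatment
OxyR	mntH	Activator	Hydrogen peroxide treatment
OxyR	oxyS	Activator	Hydrogen peroxide treatment
OxyR	sufABCDSE	Activator	Hydrogen peroxide treatment
OxyR	trxC	Activator	Hydrogen peroxide treatment
OxyR	uof-fur	Activator	Hydrogen peroxide treatment
OxyR	ychF	Repressor	Hydrogen peroxide treatment
OxyR	ahpCF	Activator	Hydrogen peroxide treatment, ascorbate treatment
OxyR	dps	Activator	Hydrogen peroxide treatment, exponential phase, stationary phase
OxyR	gntP	Repressor	Not found
OxyR	hcp-hcr	Activator	Not found
OxyR	uxuAB	Repressor	Not found
OxyR	ybjC-nfsA-rimK-ybjN	Repressor	Not found
OxyR	yhjA	Activator	Not found
OxyR	dsbG	Activator	Oxidative stress
OxyR	hemH	Activator	Oxidative stress
OxyR	oxyR	Repressor	Oxidative stress, reducing conditions
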