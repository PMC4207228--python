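tf	target	effect	gc
AraC	ara	Repressor	Absence of arabinose
ArcA	cydAB	Activator	Anaerobiosis
ArcA	gltA	Repressor	Anaerobiosis
ArcA	sdhCDAB	Repressor	Anaerobiosis, anoxic transition
ArcA	sodA	Repressor	Anaerobiosis
CRP	oxyR	Activator	Exponential phase
Fis	acs	Repressor	Exponential phase
FNR	yfgF	Activator	Anaerobiosis
FNR	yhjA	Activator	Anaerobiosis
Fur	fhuF	Repressor	Iron-rich conditions + absence of oxidative stress
Fur	mntH	Repressor	CO2 treatment, iron treatment
Fur	sufABCDSE	Repressor	Iron treatment
IHF	acs-yjcH-actP	Repressor	Stationary phase
IHF	sufABCDSE	Activator	Oxidative stress
IHF + SigmaS	dps	Activator	Stationary phase
IscR	iscRSUA	Repressor	Anaerobiosis, reactive oxygen species
MntR	dps	Repressor	Stationary phase
MntR	mntH	Repressor	Manganese treatment, iron treatment, metal treatment
MntR	mntP	Repressor	Manganese treatment
MntR	mntS	Repressor	Manganese treatment
NarL	hcp-hcr	Activator	Nitrate treatment, Nitrite treatment
NarP	hcp-hcr	Activator	Nitrate treatment, Nitrite treatment
SigmaS	aidB	Activator	Oxygen-limiting conditions
SigmaS	ansP	Activator	Onset of stationary phase
SigmaS	artIPQM	Activator	Onset of stationary phase
SigmaS	ilvD	Activator	Onset of stationary phase
SigmaS	tnaA	Activator	Onset of stationary phase
SoxS	mutM	Activator	Superoxide generators treatment
SoxS	ybjC-nfsA-rimK-ybjN	Activator	Paraquat treatment
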