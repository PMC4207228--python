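gc	effect	target
2,2'-dipyridyl treatment	Induction	mntH
2,2'-dipyridyl treatment	Inhibition	mntS
2,2'-dipyridyl treatment	Induction	isc
2,2'-dipyridyl treatment	Induction	suf
Aerobiosis	Induction	katG
Anaerobiosis	Induction	arcA
Anaerobiosis	Induction	hcp
Anaerobiosis	Inhibition	lctPRD
Anaerobiosis + nitrate treatment	Induction	hcp
Anaerobiosis + nitrite treatment	Induction	hcp
Carbon starvation	Induction	csiD
Δfur mutant	Induction	ryhB
ΔoxyR mutant	Induction	sufA
EDTA treatment	Induction	mntH
Exponential growth	Induction	bolA
Fructuronate treatment	Induction	uxuAB
Gluconate treatment	Inhibition	gntP
Glucose treatment	Inhibition	gntP
Glucose treatment	Inhibition	oxyR
Glucose treatment	Inhibition	uxuAB
Glucuronate treatment	Induction	uxuAB
Hydrogen peroxide treatment	Induction	fpr
Hydrogen peroxide treatment	Induction	iscRSUA
Hydrogen peroxide treatment	Inhibition	rplB
Hydrogen peroxide treatment	Induction	sodA
Hydrogen peroxide treatment	Induction	soxS
Hydrogen peroxide treatment	Induction	yaeH
Hydrogen peroxide treatment	Induction	ydcH
Hydrogen peroxide treatment	Induction	ydeN
Hydrogen peroxide treatment	Inhibition	yfdI
Hydrogen peroxide treatment	Induction	ygaQ
Hydrogen peroxide treatment	Induction	ytfK
Hydrogen peroxide treatment	Inhibition	fldA
Hydrogen peroxide treatment + Δfur mutant	Induction	sufA
Iron starvation	Induction	mntH
Iron starvation	Induction	isc
L-ascorbate + glutamine treatment	Induction	yiaK
L-ascorbate + proline treatment	Induction	yiaK
L-ascorbate + threonine treatment	Induction	yiaK
L-ascorbate treatment	Induction	ulaA
L-ascorbate treatment	Induction	ulaG
L-ascorbate treatment	Induction	yiaK
L-ascorbate treatment + early exponential phase	Regulation	ahpC
Mannonic amide treatment	Induction	uxuAB
Menadione treatment	Induction	ahpC
Menadione treatment	Induction	ryhB
Menadione treatment	Induction	sufA
Menadione treatment + DoxyR	Induction	sufA
Menadione treatment + DsoxRS	Induction	sufA
Menadione treatment + DsoxS	Induction	sufA
Mncl2 treatment	Induction	sodA
Nitrosative stress	Induction	hcp-hcr
Nitrosative stress	Induction	hmp
Nitrosative stress	Induction	yeaR-yoaG
Nitrosative stress	Induction	ytfE
Paraquat treatment	Induction	fldA-fur
Paraquat treatment	Induction	oxyS
Paraquat treatment	Induction	soxS
Paraquat treatment	Induction	sufA
Plumbagin treatment	Induction	sufA
PMS treatment	Induction	ahpC
PMS treatment	Induction	katG
PMS treatment	Induction	ryhB
PMS treatment + Dfur mutant	Induction	sufA
Stationary phase	Induction	katE
Stationary phase	Inhibition	oxyR
Superoxide treatment	No effect	mntH
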