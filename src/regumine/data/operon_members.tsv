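operon	gene
sufABCDSE	sufA
sufABCDSE	sufB
sufABCDSE	sufC
sufABCDSE	sufD
sufABCDSE	sufS
sufABCDSE	sufE
ahpCF	ahpC
ahpCF	ahpF
hcp-hcr	hcp
hcp-hcr	hcr
uof-fur	uof
uof-fur	fur
uxuAB	uxuA
uxuAB	uxuB
ybjC-nfsA-rimK-ybjN	ybjC
ybjC-nfsA-rimK-ybjN	nfsA
ybjC-nfsA-rimK-ybjN	rimK
ybjC-nfsA-rimK-ybjN	ybjN
iscRSUA	iscR
iscRSUA	iscS
iscRSUA	iscU
iscRSUA	iscA
acs-yjcH-actP	acs
acs-yjcH-actP	yjcH
acs-yjcH-actP	actP
cydAB	cydA
cydAB	cydB
sdhCDAB	sdhC
sdhCDAB	sdhD
sdhCDAB	sdhA
sdhCDAB	sdhB
artIPQM	artI
artIPQM	artP
artIPQM	artQ
artIPQM	artM
hemF-rcsC	hemF
hemF-rcsC	rcsC
fldA-fur	fldA
fldA-fur	fur
yeaR-yoaG	yeaR
yeaR-yoaG	yoaG
lctPRD	lctP
lctPRD	lctR
lctPRD	lctD
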