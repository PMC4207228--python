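sentence_id	structure	info	pmid
S23	OxyR [+] katG		10419964
S17	OxyR [+] katG		12644490
S165	OxyR [+] katG	Reference (PMID:2693740)	12644490
S116	OxyR [+] katG		15009899
S38	OxyR [+] katG	Reference (PMID:2693740)	1730735
S208	OxyR [+] katG	Reference	1730735
S147	OxyR [+] katG	Reference (PMID:8087856)	17464064
S157	OxyR [+] katG		17464064
S42	OxyR [?] katG		2693740
S140	OxyR [+] katG		2693740
S180	OxyR [+] katG	Evidence	2693740
S99	OxyR [?] katG		8990289
S141	OxyR [?] katG		8990289
S106	OxyR [+] katG		9324269
S27	OxyR [+] katG	Reference	11443091
S25	OxyR [+] katG	Reference	11443092
S94	OxyR [?] katG	Evidence	22539721
S118	OxyR [+] katG	Figure/Table	22539721
S20	H202 [+] katG	Reference	3045098
S20	OxyR [+] katG	Reference	3045098
S34	OxyR [?] katG	Reference	7868602
S15	OxyR [?] katG		7984106
S91	OxyR [?] katG	Reference linked	7984106
S135	OxyR [?] katG	Reference/evidence linked	8087856
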