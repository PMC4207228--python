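{"doc_id": "mntr-efflux", "title": "MntR-dependent regulation of the mntP efflux pump", "sentences": [{"text": "We also discovered that the mntP gene (formerly yebN), encoding a putative efflux pump, is upregulated by manganese through MntR."}, {"text": "Taken together, the observations that mntP is upregulated by manganese through MntR, while its deletion causes dramatic sensitivity to manganese and increased intracellular manganese levels indicate that MntP functions as an efflux pump."}, {"text": "We additionally found that expression of the mntP gene is upregulated by manganese through MntR."}, {"text": "We demonstrated MntR-dependent upregulation of mntP upon exposure to manganese (Figure 8), indicating that in addition to repressing gene expression, MntR can positively regulate transcription."}]}
{"doc_id": "oxyr-binding-modes", "title": "Two binding modes of OxyR", "sentences": [{"text": "The two binding modes probably allow OxyR to repress the oxyR and mom promoters during normal growth, while activating katG, ahpCF, dps, gorA and oxyS only upon oxidative stress."}]}
{"doc_id": "fnr-complementarity", "title": "Complementary partial statements about yfgF", "sentences": [{"text": "FNR inhibits the expression of yfgF."}, {"text": "The expression of the gene yfgF is inhibited under anaerobic conditions."}]}
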