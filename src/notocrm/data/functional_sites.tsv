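name	sequence12	mechanism
Ci-Noto1	tTTTTGGCACCT	individual
Ci-Noto9	GAcATGGCACTT	individual
Ci-Noto4	ATTTTGACACCc	individual
Ci-ABCC10	tgATTAACACCT	individual
Ci-Noto8	GTTTTAACACCa	individual
Ci-tune	tcATTTGCACTc	individual
Ci-trop	tcTCTCGCACCc	cooperative
Ci-trop	GTTTTATCACTa	cooperative
CiFCol1	cTACTAACACCa	cooperative
CiFCol1	cAAATAtCACga	cooperative
Ci-Noto5	AAAGTAACACac	cooperative
Ci-Noto5	AAACTCACACag	cooperative
Ci-ERM	tAATTAACACgT	cooperative
Ci-ERM	tAcGTCACACTa	cooperative
Ci-lamc1	cAATTCACACTT	cooperative
Ci-lamc1	AAcTTCGCACCg	cooperative
Ci-thbs3	tTATTCGCACTg	cooperative
Ci-thbs3	cgAATAACACTT	cooperative
Ci-thbs3	tgTTTCGCACgT	cooperative
Ci-leprecan	cAgTTTACACaa	cooperative
Ci-leprecan	AAAGTAtCACac	cooperative
Ci-Tbx2/3	AgATTAACACTT	cooperative
Ci-Tbx2/3	tTcTTGTCACaT	cooperative
Ci-Tbx2/3	cTTATAACACga	cooperative
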