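hexamer	status	evidence	contexts
TAACAC	required	ChIP	CiFCol1;Ci-Noto5;Ci-ABCC10;Ci-ERM;Ci-Noto8;Ci-thbs3;Ci-Tbx2/3
TCACAC	required	EMSA	Ci-leprecan;Ci-ERM;Ci-lamc1;Ci-Noto5;Ci-Noto8
TATCAC	required	EMSA	Ci-leprecan;CiFCol1;Ci-trop;Ci-Noto4
TCGCAC	required	EMSA	Ci-trop;Ci-lamc1;Ci-thbs3
TGGCAC	required	ChIP	Ci-Noto1;Ci-Noto9;Ci-thbs3;Ci-ABCC10;Ci-Noto8
TTGCAC	required	EMSA	Ci-tune;Ci-Noto8
TGACAC	required	ChIP	Ci-Noto4
TTACAC	required	EMSA	Ci-leprecan;Ci-Noto8
TGTCAC	required	ChIP	Ci-Tbx2/3;Ci-ABCC10
TTTCAC	represented_only	none	CiFCol1;Ci-ABCC10
TCTCAC	represented_only	none	Ci-ABCC10;Ci-lamc1;Ci-trop
TACCAC	represented_only	none	Ci-Noto8
TAGCAC	represented_only	none	Ci-Noto8
TCCCAC	represented_only	none	Ci-Noto4
TGCCAC	represented_only	none	Ci-ABCC10
TTCCAC	unobserved	none	
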