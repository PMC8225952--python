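OC2	CDDMCCD
OC3	C2C2D
P1	BCC,EBCCD,C2C2DC2,C2DC2C2D	C2BCC
PP1	MCCD,CCD,C2C2C2D,C2C2C2D,C2DC2C2D,C2C2DC2	C2C2C2D
P1D	HC4DC4,QQ2DRC4C,Q2C2C2DROCCDPOC	HQ2DC2C4C
P2D	CCDMC
P2F	BCCDD,BCCDFCCDFC2DEC2	BCCDD
PP3A	DRC2QQ2DDC2CCCDRC2CCCCDD
P4O	IC2D,C2C2CDC2C2D	C2C2CD
P5A	C2C2DC2,C2D	C2C2D
P5DOF	C2CCDC2C2CDC2,C2CDC2C2CD,C2C2DJKJ,J,JD,JDJ,JM,PDJP,PPP2P3P3PP2,PPP3P2PP3,PP2P3,P3P2PC3C3C4P3C3	JP
WF1	OC2CDOC2CDOC2C2DOC2
WFG2	KOC2DOC2DOC2DOC2C2DOC2C2DJD
WFG1	JD,DJDJDJDJDJDJDJPPPPP2	DJD
WF1D	P2PPP2HP3PP2PC4C4DC4DC4
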