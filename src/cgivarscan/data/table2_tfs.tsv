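gene	rsid	allele	flag	wild_tfs	variant_tfs
LDLR	rs1026272027	G/T	*	C/EBPapl	C/EBPbet
LDLR	rs887608252	C/T	*		C/EBPapl
LDLR	rs1006494933	G/A	*		GATA-1,Oct-1
LDLR	rs532491368	G/A			
LDLR	rs1024897634	C/T	*		Oct-1
MMP9	rs139620474	C/A/T—A or C/A/T—T			
MMP9	rs370018925	C/T	*		Sp1
MMP9	rs201069991	G/A			
MMP9	rs1014494202	C/T	*	Sp1	Sp1,BRF-1
MMP9	rs146719297	G/A		Sp1	Sp1
SH2B3	rs538445017	C/T		Tra-1	Tra-1
SH2B3	rs922413124	G/A	*	Sp-1	
TIMP1	rs779329701	G/A	*	Egr-1	NF-1
TIMP1	rs993047389	G/A		Sp1	Sp1
TIMP1	rs376386551	C/T	*	Sp1	N-Myc
TIMP1	rs926004266	G/A		Sp1	Sp1
APOE	rs769448	C/T	*	Sp1	
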