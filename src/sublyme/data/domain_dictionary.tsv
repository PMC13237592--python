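PF01510	EAD	Ami2 (N-acetylmuramoyl-L-alanine amidase)
PF01520	EAD	Ami3 (N-acetylmuramoyl-L-alanine amidase)
PF01464	EAD	SLT (transglycosylase SLT domain)
PF05838	EAD	GH_108 (glycoside hydrolase family 108)
PF02557	EAD	PET_M15 (VanY D-Ala-D-Ala carboxypeptidase)
PF08291	EAD	PET_M15 (peptidase M15 family)
PF13539	EAD	PET_M15 (peptidase M15 C-terminal)
PF05951	EAD	PET_M15 (peptidase M15 family)
PF01832	EAD	Glucosaminidase (mannosyl-glycoprotein endo-beta-N-acetylglucosaminidase)
PF00959	EAD	Phage lysozyme
PF13702	EAD	Lysozyme 2 (lysozyme-like domain)
PF01551	EAD	PET_M23 (peptidase M23)
PF05257	EAD	CHAP (cysteine, histidine-dependent amidohydrolase/peptidase)
PF09374	CBD	PG3 (PG_binding_3 peptidoglycan-binding domain)
PF01471	CBD	PG1 (PG_binding_1 peptidoglycan-binding domain)
PF08239	CBD	SH3_3 (bacterial SH3 domain)
PF08460	CBD	SH3_5 (bacterial SH3 domain)
PF06347	CBD	SH3_4 (bacterial SH3 domain)
PF13457	CBD	SH3_8 (bacterial SH3 domain)
PF01476	CBD	LysM (lysin motif)
PF00877	CBD	Cpl-7 lysozyme C-terminal (cell-wall binding)
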