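name	signature	label	experimentally_studied
Op_MAL1/Opp_AG1	FTAGLVGDN	maltase-isomaltase	yes
Le_AG1	HTAGMVGDN	maltase-isomaltase	yes
ancMALS	FTAGLVGDE	maltase-isomaltase	yes
Sc_MAL12/Sc_MAL32/Sc_MAL62	FTAGLVAED	maltase	yes
Sc_IMA1/Sc_IMA2	YVGSLMQDE	isomaltase	yes
Sc_IMA3/4	YVGSLMRDE	isomaltase	yes
Sc_IMA5	FVGSMVGSE	isomaltase	yes
Td_AG1	YVGSLMQDE	isomaltase	no
Cf_AG1.2	HTAGLVGDN	maltase-isomaltase	no
Cf_AG1.1	MVCSLVGSQ	isomaltase	no
Ss_MAL6	YTAGLVGNN	maltase-isomaltase	no
Ss_MAL7	FTAGLVGTN	maltase-isomaltase	no
Ss_MAL8	YTAGLVGEN	maltase-isomaltase	no
Ss_MAL9	YTAGMVGEN	maltase-isomaltase	no
Ss_AGL1	YTAGLVGWN	maltase-isomaltase	no
Mg_AG2	YTAGMVGDN	maltase-isomaltase	no
Mg_AG1	CVAALVGEE	isomaltase	no
Ls_AG1	YTVNKLSHE	maltase	no
Ls_AG6	NTVNRLPGR	maltase	no
Ba_AG2	YTVQIGSRN	maltase	yes
Ao_MalT	ITVNMLPDD	maltase	yes
Ls_AG2	LAINFMADE	maltase	no
Ls_AG4	HAINFMGTE	maltase	no
Ls_AG5	AAINFMADE	maltase	no
Sp_Mal1	YAINMMPDE	maltase	yes
Bs_maltase	IAISHANGA	maltase	yes
Ls_AG3	CVINFMPDE	isomaltase	no
Ls_AG7	EVINYMGQE	isomaltase	no
Ls_AG8	-VINFMPDE	isomaltase	no
Dh_AG1	AVINFMPDE	isomaltase	no
Ba_AG1	YVINLMPQE	isomaltase	no
Bt_isomaltase	VVINMTPDE	isomaltase	yes
An_AgdC	FVINFMPDD	isomaltase	yes
Fo_Foagl1	FVINFMPDD	isomaltase	yes
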