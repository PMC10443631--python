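interaction_id	ligand	receptor
PECAM1_CD177	Pecam1	Cd177
CD74_MIF	Cd74	Mif
IL1B_ADRB2	Il1b	Adrb2
CCL4_CCR5	Ccl4	Ccr5
CXCL2_DPP4	Cxcl2	Dpp4
CD28_CD86	Cd28	Cd86
CXCL12_CXCR4	Cxcl12	Cxcr4
TNF_TNFRSF1A	Tnf	Tnfrsf1a
IL6_IL6RA	Il6	Il6ra
CSF1_CSF1R	Csf1	Csf1r
KITL_KIT	Kitl	Kit
CCL2_CCR2	Ccl2	Ccr2
CXCL1_CXCR2	Cxcl1	Cxcr2
TGFB1_TGFBR1	Tgfb1	Tgfbr1
IL10_IL10RA	Il10	Il10ra
CCL5_CCR1	Ccl5	Ccr1
VCAM1_ITGA4	Vcam1	Itga4
ICAM1_ITGB2	Icam1	Itgb2
SELE_SELPLG	Sele	Selplg
CX3CL1_CX3CR1	Cx3cl1	Cx3cr1
FLT3L_FLT3	Flt3l	Flt3
ANGPT1_TEK	Angpt1	Tek
JAG1_NOTCH1	Jag1	Notch1
DLL1_NOTCH2	Dll1	Notch2
VEGFA_KDR	Vegfa	Kdr
IL7_IL7R	Il7	Il7r
CCL19_CCR7	Ccl19	Ccr7
CD40LG_CD40	Cd40lg	Cd40
FASL_FAS	Fasl	Fas
LGALS9_HAVCR2	Lgals9	Havcr2
CCL4_CCR1	Ccl4	Ccr1
CCL5_CCR5	Ccl5	Ccr5
CCL2_CCR5	Ccl2	Ccr5
CXCL12_DPP4	Cxcl12	Dpp4
IL1B_IL6RA	Il1b	Il6ra
TNF_FAS	Tnf	Fas
TGFB1_ITGB2	Tgfb1	Itgb2
MIF_CXCR4	Mif	Cxcr4
MIF_CXCR2	Mif	Cxcr2
CD74_CD44	Cd74	Cd44
IL18_IL18R1	Il18	Il18r1
IL1A_IL1R1	Il1a	Il1r1
IL1B_IL1R1	Il1b	Il1r1
IL1RN_IL1R1	Il1rn	Il1r1
IL4_IL4RA	Il4	Il4ra
IL13_IL4RA	Il13	Il4ra
IFNG_IFNGR1	Ifng	Ifngr1
IL11_IL11RA1	Il11	Il11ra1
CXCL1_DPP4	Cxcl1	Dpp4
SELE_CD44	Sele	Cd44
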