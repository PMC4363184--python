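# category	tag	id	pattern
# tag: kinase-signature anchor slot (N1..N9, C1..C3), MAPK group for
# group-specific motifs, or "-" when not applicable.  Two spellings of the
# catalytic-loop/DFG signature circulate; both are shipped under slot N9
# and either satisfies the anchor.
nterm_txy	D	nterm_TEY	T-E-Y
nterm_txy	D	nterm_TDY	T-D-Y
nterm_txy	D	nterm_SEY	S-E-Y
nterm_txy	D	nterm_SDY	S-D-Y
nterm_txy	D	nterm_AVH	A-V-H
nterm_secondary	A	nsec_AKY	A-K-Y
nterm_secondary	A	nsec_NKY	N-K-Y
nterm_secondary	B	nsec_SKY	S-K-Y
nterm_secondary	B	nsec_RKY	R-K-Y
nterm_secondary	C	nsec_TKY	T-K-Y
nterm_secondary	D	nsec_SQY	S-Q-Y
nterm_secondary	D	nsec_NRY	N-R-Y
nterm_secondary	D	nsec_SRY	S-R-Y
kinase_signature	N1	sig_glycine_rich	I-G-x-G-x-Y-G-x-V
kinase_signature	N2	sig_ikki	I-K-K-I-x_3-F
kinase_signature	N3	sig_daxrxlre	D-A-x-R-x-L-R-E
kinase_signature	N4	sig_fxdiy	F-x-D-I-Y-x_3-E-L-M
kinase_signature	N5	sig_dlxxvi	D-L-x_2-V-I
kinase_signature	N6	sig_dxlxxeh	D-x-L-x_2-E-H
kinase_signature	N7	sig_qxlrxlkyxh	Q-x-L-R-x-L-K-Y-x-H
kinase_signature	N8	sig_catalytic_hrd	H-R-D-L-K-P-x-N
kinase_signature	N9	sig_dfg_table	L-x-N-x-N-C-x-L-K-I-x-D-F-G-L-A-R
kinase_signature	N9	sig_dfg_text	L-x-L-x-N-C-x-L-K-I-x-D-F-G-L-A-R
kinase_signature	C1	sig_apel	T-R-W-Y-R-A-P-E-L
kinase_signature	C2	sig_idxws	I-D-x-W-S-I/V-G-C
kinase_signature	C3	sig_qxllxfdp	Q-x-L-L-x-F-D-P
activation_loop	-	loop_TEY	T-E-Y
activation_loop	-	loop_TDY	T-D-Y
activation_loop	-	loop_MEY	M-E-Y
activation_loop	-	loop_TEM	T-E-M
activation_loop	-	loop_TQM	T-Q-M
activation_loop	-	loop_TRM	T-R-M
activation_loop	-	loop_TVY	T-V-Y
activation_loop	-	loop_TSY	T-S-Y
activation_loop	-	loop_TEC	T-E-C
activation_loop	-	loop_TQY	T-Q-Y
cterm_postloop	-	cpost_SDY	S-D-Y
cterm_postloop	-	cpost_SEY	S-E-Y
cterm_postloop	-	cpost_TDY	T-D-Y
cterm_postloop	-	cpost_DNY	D-N-Y
cterm_postloop	-	cpost_SQY	S-Q-Y
cterm_postloop	-	cpost_SKY	S-K-Y
cterm_postloop	-	cpost_SRY	S-R-Y
cterm_postloop	-	cpost_SNY	S-N-Y
cterm_postloop	-	cpost_TKY	T-K-Y
cd_site	A	cd_group_A	K-M-L-T-F-D-P-K/R-Q/K-R-I-T-V-E-D/E-A-L
cd_site	B	cd_group_B	K-M-L-V/I-F-D-P-x-K-R-I-I-V-D-E-A-L
cd_site	C	cd_group_C	K-M-L-I-F-D-P-S/T-K-R-I-S-V-T-E-A-L
cd_site	D	cd_group_D	L-L-E-R/K-L-L-A-F-D-P-K-D-R-P-T-A-E-E-A-L
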