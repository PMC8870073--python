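gene	aa_change	clinvar	varsome	oncokb	treatment
IDH2	R261H	Benign/likely benign	Benign	Unknown effect	/
IDH2	R131H	Benign/likely benign	Benign	Unknown effect	/
IDH2	R209H	Benign/likely benign	Benign	Unknown effect	/
RAD51B	T107K	/	Uncertain significance	Unknown effect	/
TP53	Y220N	Conflicting interpretations of pathogenicity	Pathogenic	Likely oncogenic	/
TP53	Y127N	/	Pathogenic	Likely oncogenic	/
TP53	Y88N	Conflicting interpretations of pathogenicity	Pathogenic	Unknown effect	/
BRCA2	E394A	Benign	Likely benign	Unknown effect	/
BRIP1	P47A	Conflicting interpretations of pathogenicity	Likely pathogenic	Oncogenic (loss of function)	Level 3B; FDA Level 2 (prostate cancer and NOS: olaparib)
BRAF	L319I	/	/	Unknown effect	/
TP53	R141H	Pathogenic	Pathogenic	Likely oncogenic	/
ATM	E2156D	/	Uncertain significance	Unknown effect	/
PTEN	Y155C	Pathogenic	Pathogenic	Oncogenic (loss of function)	Level 4; FDA level 3 (all solid tumors: AZD8186, GSK2636771)
ROS1	G374A	/	Uncertain significance	Unknown effect	/
ROS1	G365A	Likely pathogenic	Uncertain significance	Unknown effect	/
TP53	L17R	/	/	Unknown effect	/
TP53	L198R	/	Uncertain significance	Likely oncogenic	/
TP53	L330R	/	Likely pathogenic	Likely oncogenic	/
BARD1	R207C	Conflicting interpretations of pathogenicity	Benign	Unknown effect	/
TP53	V125G	/	Pathogenic	Likely oncogenic	/
TP53	V86G	Uncertain significance	Pathogenic	Unknown effect	/
TP53	V218G	Uncertain significance	Pathogenic	Likely oncogenic	/
ALK	R405H	/	Uncertain significance	Unknown effect	/
ALK	R1575H	Uncertain significance	Uncertain significance	Unknown effect	/
ATM	L89F	/	Benign	Unknown effect	/
CHEK2	K373E	Conflicting interpretations of pathogenicity	Uncertain significance	Oncogenic (loss of function)	Level 3B; FDA Level 2 (prostate cancer and NOS: olaparib)
CHEK2	K117E	/	/	Unknown effect	/
CHEK2	K344E	Conflicting interpretations of pathogenicity	Uncertain significance	Unknown effect	/
CHEK2	K152E	Conflicting interpretations of pathogenicity	Uncertain significance	Unknown effect	/
CHEK2	K416E	Conflicting interpretations of pathogenicity	Uncertain significance	Unknown effect	/
CHEK2	K282E	Uncertain significance	Uncertain significance	Unknown effect	/
FGFR3	P449S	Benign/likely benign	Benign	Unknown effect	/
FGFR3	P450S	Benign/likely benign	Benign	Unknown effect	/
FGFR3	P451S	Benign/likely benign	Benign	Unknown effect	/
NF1	D109E	/	/	Unknown effect	/
TP53	V157F	Conflicting interpretations of pathogenicity	Pathogenic	Likely oncogenic	/
TP53	V25F	Conflicting interpretations of pathogenicity	Pathogenic	Unknown effect	/
TP53	V64F	/	Pathogenic	Unknown effect	/
TP53	Y163C	Pathogenic	Pathogenic	Likely oncogenic	/
TP53	Y31C	Pathogenic	Pathogenic	Unknown effect	/
TP53	Y70C	/	Pathogenic	Unknown effect	/
ATM	P1054R	Benign/likely benign	Benign	Likely neutral	/
PTEN	Y27C	Likely pathogenic	Pathogenic	Likely oncogenic	Level 4 (all solid tumors: AZD8186, GSK2636771)
TP53	S127Y	Pathogenic	Pathogenic	Likely oncogenic	/
TP53	S34Y	/	Pathogenic	Unknown effect	/
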