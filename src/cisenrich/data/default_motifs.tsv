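# Default TF-binding-site registry: name<TAB>IUPAC word
GRE	BACGTV
TGA	TGACG
AC	ACTCAT
AUX1	TGTCTC
AUX2	TGTCYS
RY	CATGCATG
MRE1	AMCWAMC
MRE2	GGWTW
MYC2	CACATG
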