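name	pattern	category
ABRE	ACGTGGC	abscisic acid responsiveness
ABRE-core	ACGTG	abscisic acid responsiveness
CE3	GACGCGTGTC	abscisic acid responsiveness
motif-IIb	CCGCCGCGCT	abscisic acid responsiveness
TCA-element	CCATCTTTTT	salicylic acid responsiveness
CA-element	CAACAAC	salicylic acid responsiveness
CGTCA-motif	CGTCA	methyl jasmonate responsiveness
TGACG-motif	TGACG	methyl jasmonate responsiveness
ERE	ATTTCAAA	ethylene responsiveness
AuxRR-core	GGTCCAT	auxin responsiveness
TGA-element	AACGAC	auxin responsiveness
AuxRE	TGTCTC	auxin response element
P-box	CCTTTTG	gibberellin responsiveness
TATC-box	TATCCCA	gibberellin responsiveness
GARE-motif	TCTGTTG	gibberellin responsiveness
LTR	CCGAAA	low-temperature responsiveness
HSE	AAAAAATTTC	heat stress responsiveness
TC-rich-repeats	ATTTTCTTCA	defense and stress responsiveness
DRE-CRT	RCCGAC	dehydration responsiveness
W-box	TTGACC	WRKY binding, pathogen defense
Skn-1-motif	GTCAT	endosperm-specific expression
GCN4-motif	TGAGTCA	endosperm-specific expression
RY-element	CATGCATG	seed-specific regulation
as-1	TGACGTCA	root-specific expression
motif-I	CAGTTA	root-specific expression
HD-Zip1	CAATNATTG	palisade mesophyll differentiation
HD-Zip2	CAATSATTG	cell differentiation
MRE	AACCTAA	light responsiveness, MYB binding
ACE	GACACGTATG	light responsiveness
Box-4	ATTAAT	light responsiveness
Box-I	TTTCAAA	light responsiveness
G-box	CACGTG	light responsiveness
GT1-motif	GGTTAA	light responsiveness
I-box	GATAAG	light responsiveness
MBS	CAACTG	MYB binding, drought inducibility
MYB-recognition	WAACCA	MYB binding
E-box	CANNTG	bHLH binding
GAGA-repeat	GAGAGAGAGA	GAGA-factor binding
CAAT-box	CCAAT	common promoter element
TATA-box	TATAWAW	core promoter element
de-novo-candidate	GGTTGAATACAC	candidate element recovered by enumerative discovery
known-similar	GATGGAATAC	candidate element, known similar motif
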