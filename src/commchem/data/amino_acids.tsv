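# Physicochemical constants for the 20 standard amino acids.
# c,h,n,o,s: atom counts of the FREE amino acid (residue = free minus H2O).
# hydropathy: Kyte-Doolittle scale. pk/pk_class: side-chain ionization
# (Bjellqvist-style values; '.' = side chain not ionizable).
# Edit or replace this file to swap the pK or hydropathy tables.
code3	code1	c	h	n	o	s	hydropathy	pk	pk_class
Ala	A	3	7	1	2	0	1.8	.	.
Arg	R	6	14	4	2	0	-4.5	12.0	base
Asn	N	4	8	2	3	0	-3.5	.	.
Asp	D	4	7	1	4	0	-3.5	4.05	acid
Cys	C	3	7	1	2	1	2.5	9.0	acid
Gln	Q	5	10	2	3	0	-3.5	.	.
Glu	E	5	9	1	4	0	-3.5	4.45	acid
Gly	G	2	5	1	2	0	-0.4	.	.
His	H	6	9	3	2	0	-3.2	5.98	base
Ile	I	6	13	1	2	0	4.5	.	.
Leu	L	6	13	1	2	0	3.8	.	.
Lys	K	6	14	2	2	0	-3.9	10.0	base
Met	M	5	11	1	2	1	1.9	.	.
Phe	F	9	11	1	2	0	2.8	.	.
Pro	P	5	9	1	2	0	-1.6	.	.
Ser	S	3	7	1	3	0	-0.8	.	.
Thr	T	4	9	1	3	0	-0.7	.	.
Trp	W	11	12	2	2	0	-0.9	.	.
Tyr	Y	9	11	1	3	0	-1.3	10.0	acid
Val	V	5	11	1	2	0	4.2	.	.
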