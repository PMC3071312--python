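# Transcription of the published clone-resequencing mutation catalog (three clone sections:
# 20 mutations shared by G3.2/G3.6, 8 in G3.266.7, 11 in X3.5). Coordinates are 1-based
# positions in the ancestral reference genome; "-" marks values not printed in the source.
carrier	gene	coordinate	class	nt_change	protein_change
G3.2/G3.6	phoQ	1197581	SNP	A>G	L209P
G3.2/G3.6	acrB	480665	SNP	G>A	P988L
G3.2/G3.6	queA	425270	SNP	A>G	N346D
G3.2/G3.6	secA	108975	SNP	T>C	S233P
G3.2/G3.6	cadA	4363790	SNP	A>G	I686T
G3.2/G3.6	groL	4378650	SNP	A>C	K132N
G3.2/G3.6	mutL	4405650	short-indel	-19bp	Frameshift
G3.2/G3.6	pstC	3917582	SNP	T>C	D16G
G3.2/G3.6	rph	3823229	short-indel	+4:GGTC	Frameshift
G3.2/G3.6	yiaK	3750540	SNP	T>C	L193P
G3.2/G3.6	gltD	3367270	short-indel	+1:G	Frameshift
G3.2/G3.6	mdh	3390726	short-indel	-1:C	Frameshift
G3.2/G3.6	nlpI	3316213	SNP	T>C	Non-coding; possible effect on terminator before nlpI
G3.2/G3.6	glnE	3205272	SV	IS186 insertion	Disruption
G3.2/G3.6	hybB	3150318	SNP	A>G	V359A
G3.2/G3.6	gatZ	2182915	short-indel	-1:C	Frameshift
G3.2/G3.6	yeeE	2092513	SNP	A>G	S333P
G3.2/G3.6	lepB	2711902	SNP	G>A	P213S
G3.2/G3.6	hfq	4407505	short-indel	-7:AGGAAAA	Non-coding; ribosome binding site deletion
G3.2/G3.6	marC	1625925	SV	IS1 insertion	Disruption
G3.266.7	groL	4378650	SNP	A>C	K132N
G3.266.7	rph	3823229	short-indel	+4:GGTC	Frameshift
G3.266.7	gltB-yhcE	-	SV	-9.9kb	deletion of gltBDF and yhcADE
G3.266.7	mdh	3390726	short-indel	-1:C	Frameshift
G3.266.7	glnE	3205272	SV	IS186 insertion	Disruption
G3.266.7	hfq	4407505	short-indel	-7:AGGAAAA	Non-coding; ribosome binding site deletion
G3.266.7	ycfK	1216432	SV	-1688bp	deletion of ycfK
G3.266.7	marC	1625925	SV	IS1 insertion	Disruption
X3.5	acrA	483735	short-indel	+1:A	Frameshift
X3.5	rpsB	190557	short-indel	+1:A	Frameshift
X3.5	rph	-	short-indel	-1:C	Frameshift
X3.5	mdh	3390936	short-indel	+5:AACCT	Frameshift
X3.5	deaD	3314027	short-indel	+4:AGAC	Frameshift
X3.5	yfgO	2623022	SNP	C>T	G30D
X3.5	gatC	2180640	SNP	C>T	E290K
X3.5	plsX	1493514	SNP	A>G	E216G
X3.5	hrpA	1493514	SNP	C>T	L1075L
X3.5	mdtJ-tqsA	1681114	SV	IS5 insertion	Non-coding; mdtJ and tqsA promoter region
X3.5	marC	1626081	SV	IS1 insertion	Disruption
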