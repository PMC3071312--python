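# Transcription of the endpoint-population parallel-evolution survey: one row per
# (population, gene) mutation detected by Sanger sequencing of acrA, acrB, tolC, mdh,
# hfq and marC across the six independently evolved populations. tolC carried no
# mutations in any population, so it contributes no rows.
population	gene	coordinate	change
X1	acrB	481310	A>C (V773G)
X1	hfq	4407590	T>G (I24M)
X1	marC	1625925	IS1 insertion (Disruption)
X2	acrA	484383	T>G (N154T)
X2	mdh	3390659	+4:GATT (Frameshift)
X2	marC	1626084	IS5 insertion (Disruption)
X3	acrA	483735	+1:A (Frameshift)
X3	mdh	3390936	+5:AACCT (Frameshift)
X3	marC	1626081	IS1 insertion (Disruption)
G1	acrA	484669	G>T (R59S)
G1	marC	1625925	IS1 insertion (Disruption)
G2	marC	1626100	-6:CCACCA (Deletion of V13 and V14)
G3	acrB	480665	G>A (P988L)
G3	mdh	3390726	-1:C (Frameshift)
G3	hfq	4407505	-7:AGGAAAA (RBS deletion)
G3	marC	1625925	IS1 insertion (Disruption)
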