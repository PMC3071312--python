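# SYNTHETIC-IN-PART fixture: whole-population allele states of the X3 lineage at
# genotyped generations. Only two first-detection generations are anchored by published
# observations: the mdtJ-tqsA intergenic insertion at generation 180 and the mdh/deaD/plsX
# cluster at generation 266. All other first-detection generations below (the early
# marC/gatC/hrpA/yfgO cluster at 90, rph at 135, rpsB at 310, acrA at 355) are synthetic
# placeholders that encode only the ordinal structure; acrA remains Mixed at the end,
# matching its ~50% final allele frequency.
locus	generation	state
marC	0	WT
marC	90	Mixed
marC	135	Mut
marC	180	Mut
marC	266	Mut
marC	310	Mut
marC	355	Mut
marC	430	Mut
gatC	0	WT
gatC	90	Mixed
gatC	135	Mut
gatC	180	Mut
gatC	266	Mut
gatC	310	Mut
gatC	355	Mut
gatC	430	Mut
hrpA	0	WT
hrpA	90	Mixed
hrpA	135	Mut
hrpA	180	Mut
hrpA	266	Mut
hrpA	310	Mut
hrpA	355	Mut
hrpA	430	Mut
yfgO	0	WT
yfgO	90	Mixed
yfgO	135	Mut
yfgO	180	Mut
yfgO	266	Mut
yfgO	310	Mut
yfgO	355	Mut
yfgO	430	Mut
rph	0	WT
rph	90	WT
rph	135	Mixed
rph	180	Mut
rph	266	Mut
rph	310	Mut
rph	355	Mut
rph	430	Mut
mdtJ-tqsA	0	WT
mdtJ-tqsA	90	WT
mdtJ-tqsA	135	WT
mdtJ-tqsA	180	Mixed
mdtJ-tqsA	266	Mut
mdtJ-tqsA	310	Mut
mdtJ-tqsA	355	Mut
mdtJ-tqsA	430	Mut
mdh	0	WT
mdh	90	WT
mdh	135	WT
mdh	180	WT
mdh	266	Mixed
mdh	310	Mut
mdh	355	Mut
mdh	430	Mut
deaD	0	WT
deaD	90	WT
deaD	135	WT
deaD	180	WT
deaD	266	Mixed
deaD	310	Mut
deaD	355	Mut
deaD	430	Mut
plsX	0	WT
plsX	90	WT
plsX	135	WT
plsX	180	WT
plsX	266	Mixed
plsX	310	Mut
plsX	355	Mut
plsX	430	Mut
rpsB	0	WT
rpsB	90	WT
rpsB	135	WT
rpsB	180	WT
rpsB	266	WT
rpsB	310	Mixed
rpsB	355	Mut
rpsB	430	Mut
acrA	0	WT
acrA	90	WT
acrA	135	WT
acrA	180	WT
acrA	266	WT
acrA	310	WT
acrA	355	Mixed
acrA	430	Mixed
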