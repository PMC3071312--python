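# Totals of mutations discovered across all four resequenced clones (X3.5, G3.2, G3.6,
# G3.266.7), by mutation class, as reported for the full catalog.
class	count
SNP	96
short-indel	25
SV	10
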