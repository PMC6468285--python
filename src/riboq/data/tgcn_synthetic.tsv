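# Synthetic tRNA gene copy number table (anticodons written 5'->3', DNA).
# A constructed stand-in with a realistic eukaryotic anticodon repertoire and
# copy numbers; replace with an organism's gtRNAdb export for real analyses.
anticodon	gene_copy_number
AGC	11
TGC	5
CGC	1
ACG	6
TCG	1
CCG	1
TCT	11
CCT	1
GTT	10
GTC	16
GCA	4
TTG	9
CTG	1
TTC	14
CTC	2
GCC	16
TCC	3
CCC	2
GTG	7
AAT	13
TAT	2
TAA	7
CAA	10
AAG	7
TAG	2
CAG	1
TTT	7
CTT	14
CAT	5
GAA	10
AGG	10
TGG	2
CGG	1
AGA	11
TGA	3
CGA	1
GCT	2
AGT	11
TGT	4
CGT	1
CCA	6
GTA	8
AAC	14
TAC	2
CAC	2
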