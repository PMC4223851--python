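codon	per_thousand
TTT	12.6
TTC	22.3
TTA	4.2
TTG	14.6
CTT	8.4
CTC	14.3
CTA	7.6
CTG	42.0
ATT	16.3
ATC	24.0
ATA	8.2
ATG	23.3
GTT	9.4
GTC	14.0
GTA	5.4
GTG	27.4
TCT	7.2
TCC	21.3
TCA	8.7
TCG	17.9
CCT	6.3
CCC	17.2
CCA	13.3
CCG	17.0
ACT	7.8
ACC	22.0
ACA	9.5
ACG	14.0
GCT	12.6
GCC	33.3
GCA	12.4
GCG	12.2
TAT	9.3
TAC	18.2
TAA	0.0
TAG	0.0
TGA	0.0
CAT	9.4
CAC	15.4
CAA	14.5
CAG	34.4
AAT	19.5
AAC	25.2
AAA	15.4
AAG	36.4
GAT	26.3
GAC	23.9
GAA	18.2
GAG	40.0
TGT	5.1
TGC	12.3
TGG	10.0
CGT	8.4
CGC	17.1
CGA	7.3
CGG	8.0
AGT	9.4
AGC	19.8
AGA	4.2
AGG	5.2
GGT	12.0
GGC	25.8
GGA	17.0
GGG	3.8
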