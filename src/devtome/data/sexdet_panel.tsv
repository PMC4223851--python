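# Sex-determination gene panel (D. melanogaster pathway members) used to
# screen transcriptomes by protein alignment. peptide_ids are the panel
# peptide identifiers expected as subjects in the screening hit table.
gene	n_peptides
Sxl	9
tra	2
tra2	7
dsx	5
fru	12
N	2
ix	2
her	1
snf	1
vir	2
fl2d	2
Spf45	1
dpn	1
emc	1
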