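# Cytochrome P450 families expected in tephritid/drosophilid transcriptomes.
# Family labels are normalized Arabic names (CYP4, CYP6, ...); gene-name
# patterns in annotation tables may use Roman numerals (CYPVI) or mixed-case
# clan-style names (Cyp6a2) — both are normalized before lookup.
family
CYP3
CYP4
CYP6
CYP9
CYP12
CYP18
CYP28
CYP49
CYP301
CYP303
CYP304
CYP305
CYP306
CYP307
CYP308
CYP309
CYP310
CYP311
CYP313
CYP314
CYP315
CYP317
CYP318
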