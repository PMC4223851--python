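# Pfam-domain-name patterns mapped to transcription-factor domain classes.
# Rows are in priority order: a transcript with domains matching several
# classes is assigned the first matching class. Patterns are case-insensitive
# substrings matched against Pfam domain names.
pattern	tf_class
zf-	Zinc finger
zinc_finger	Zinc finger
Homeo	Homeobox
HLH	Helix-loop-helix
BTB	BTB/POZ
bZIP	Bzip
Myb	Myb
WD40	WD40
TBP	Basal TFs
TAF	Basal TFs
TFII	Basal TFs
Fork	Fork-head
Bromo	Bromodomain
Helicase	Helicase
DEAD	Helicase
SNF2	Helicase
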