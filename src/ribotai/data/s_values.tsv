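# Codon:anticodon pairing-class selective constraints (dos Reis-style s-values)
# for prokaryotes. Class key is "<codon third base>:<anticodon wobble base>",
# with A34 treated as inosine when reading C- or A-ending codons.
pairing_class	s
U:A	0.0
C:G	0.0
A:U	0.0
G:C	0.0
U:G	0.41
C:I	0.28
A:I	0.9999
G:U	0.68
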