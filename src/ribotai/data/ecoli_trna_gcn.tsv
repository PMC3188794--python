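# tRNA gene copy numbers by anticodon (5'->3', RNA alphabet), approximating the
# E. coli K-12 repertoire. Repo-bundled default parameter table, not deposited
# experimental data. The lysidine-modified Ile2 tRNA (annotated anticodon CAU) is
# omitted so that the generic wobble rules do not credit it to AUG; codon AUA is
# therefore weight-imputed downstream.
anticodon	copy_number
UGC	3
GGC	2
ACG	4
CCG	1
CCU	1
UCU	1
GUU	4
GUC	3
GCA	1
UUG	2
CUG	2
UUC	4
GCC	4
CCC	1
UCC	1
GUG	1
GAU	3
CAG	4
GAG	1
UAG	1
CAA	1
UAA	1
UUU	6
CAU	6
GAA	2
CGG	1
GGG	1
UGG	1
CGA	1
GCU	1
GGA	2
UGA	1
CGU	1
GGU	2
UGU	1
CCA	1
GUA	3
GAC	2
UAC	5
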