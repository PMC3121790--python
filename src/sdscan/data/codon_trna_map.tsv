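# Simplified codon -> tRNA mapping from standard wobble rules:
# anticodon position 34 G reads NNU/NNC, U reads NNA, C reads NNG.
# Editable: replace with an organism-specific decoding table as needed.
codon	trna
AAA	tRNA-K-TTT
AAC	tRNA-N-GTT
AAG	tRNA-K-CTT
AAT	tRNA-N-GTT
ACA	tRNA-T-TGT
ACC	tRNA-T-GGT
ACG	tRNA-T-CGT
ACT	tRNA-T-GGT
AGA	tRNA-R-TCT
AGC	tRNA-S-GCT
AGG	tRNA-R-CCT
AGT	tRNA-S-GCT
ATA	tRNA-I-TAT
ATC	tRNA-I-GAT
ATG	tRNA-M-CAT
ATT	tRNA-I-GAT
CAA	tRNA-Q-TTG
CAC	tRNA-H-GTG
CAG	tRNA-Q-CTG
CAT	tRNA-H-GTG
CCA	tRNA-P-TGG
CCC	tRNA-P-GGG
CCG	tRNA-P-CGG
CCT	tRNA-P-GGG
CGA	tRNA-R-TCG
CGC	tRNA-R-GCG
CGG	tRNA-R-CCG
CGT	tRNA-R-GCG
CTA	tRNA-L-TAG
CTC	tRNA-L-GAG
CTG	tRNA-L-CAG
CTT	tRNA-L-GAG
GAA	tRNA-E-TTC
GAC	tRNA-D-GTC
GAG	tRNA-E-CTC
GAT	tRNA-D-GTC
GCA	tRNA-A-TGC
GCC	tRNA-A-GGC
GCG	tRNA-A-CGC
GCT	tRNA-A-GGC
GGA	tRNA-G-TCC
GGC	tRNA-G-GCC
GGG	tRNA-G-CCC
GGT	tRNA-G-GCC
GTA	tRNA-V-TAC
GTC	tRNA-V-GAC
GTG	tRNA-V-CAC
GTT	tRNA-V-GAC
TAC	tRNA-Y-GTA
TAT	tRNA-Y-GTA
TCA	tRNA-S-TGA
TCC	tRNA-S-GGA
TCG	tRNA-S-CGA
TCT	tRNA-S-GGA
TGC	tRNA-C-GCA
TGG	tRNA-W-CCA
TGT	tRNA-C-GCA
TTA	tRNA-L-TAA
TTC	tRNA-F-GAA
TTG	tRNA-L-CAA
TTT	tRNA-F-GAA
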