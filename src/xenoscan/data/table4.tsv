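gene	block	sequence
ABCC1	18	5′-CUC​CCU​GCG​CCG​CCG​CCG​CCG​CCG​CCG​CAG​CGC​U-3′
ASH1L	18	5′-CUG​CUG​CUG​CCG​CCG​CCG​CCG​CCG​CCG​CUC​CCG​C-3′
BTF3L4	18	5′-CUG​CUC​CCG​CCG​CCG​CCG​CCG​CCG​CCG​UCG​UCU​U-3′
C2CD4C	18	5′-ACU​GCG​CUG​CCG​CCG​CCG​CCG​CCG​CCC​GCA​UCG​A-3′
CPT1A	18	5′-ACU​CCA​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CUG​CCG​C-3′
EGLN1	18	5′-UCG​CCG​UCG​CCG​CCG​CCG​CCG​CCG​CCA​UGG​CCA​A-3′
GRIN1	18	5′-UCC​GCG​GAG​CCG​CCG​CCG​CCG​CCG​CCG​GGC​CCU​U-3′
GTF2E2	18	5′-CCG​CCG​CUG​CCG​CCG​CCG​CCG​CCG​CCA​CCG​CCA​G-3′
MAST1	18	5′-CUC​CCC​GCG​CCG​CCG​CCG​CCG​CCG​CCU​CCG​CCG​C-3′
MEMO1	18	5′-CCG​CUC​CUG​CCG​CCG​CCG​CCG​CCG​CCU​CCU​CAU​U-3′
MPRIP	18	5′-AGG​CCU​GCG​CCG​CCG​CCG​CCG​CCG​CCG​UCG​CCG​C-3′
NOG	18	5′-GCG​CGG​ACG​CCG​CCG​CCG​CCG​CCG​CCG​CUG​GAG​U-3′
RIMS4	18	5′-AGC​CGC​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CGG​CCG​A-3′
RNF165	18	5′-CGC​GCG​CAG​CCG​CCG​CCG​CCG​CCG​CCG​CGC​GAG​G-3′
RNF220	18	5′-CUG​CCG​CUG​CCG​CCG​CCG​CCG​CCG​CCG​CUG​CCU​C-3′
SCAP	18	5′-CCC​CCG​UCG​CCG​CCG​CCG​CCG​CCG​CCG​CAG​CUU​G-3′
SEPHS1	18	5′-GGG​CCC​CCG​CCG​CCG​CCG​CCG​CCG​CCG​GGC​GCG​G-3′
SPEN	18	5′-CCG​CCG​CAG​CCG​CCG​CCG​CCG​CCG​CCC​CGG​CAC​C-3′
ABCD3	21	5′-GTA​AGG​UAG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CGU​CCC​C-3′
ANKH	21	5′-AAC​CUU​CUG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​UCC​CTC​C-3′
ANKRD13D	21	5′-GCC​CCG​CUG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CUA​CTG​C-3′
C4orf19	21	5′-GGG​ACC​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​UCU​GGC​C-3′
CA10	21	5′-UGG​CUG​CUG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CUG​CTA​G-3′
DISP2	21	5′-CCG​CCA​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CGG​CTT​C-3′
HS3ST4	21	5′-CGG​GGG​CUG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CGA​GCC​G-3′
JARID2	21	5′-GUG​GUG​CUG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CUG​GAG​T-3′
RGP1	21	5′-CAG​CGG​ACG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CGU​ACC​T-3′
UBE2R2	21	5′-GGC​CCG​GCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CGA​UGG​C-3′
USP25	21	5′-GCG​CCA​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CGG​GGG​C-3′
AFF2	24	5′-CAG​CCG​CUG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CGC​CGC​C-3′
CUL3	24	5′-GAG​UCC​GAG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCC​CCG​CCG​C-3′
FAM50A	24	5′-CGC​CGC​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CUG​CCA​U-3′
GSK3B	24	5′-GGG​CUU​GUG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCC​GGG​CCA​A-3′
MAP2K3	24	5′-CCG​CAG​UCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CUG​CUC​C-3′
MSI1	24	5′-CGC​CGA​GCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CUC​CGC​U-3′
MTHFD1L	24	5′-UCC​UUC​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCU​GCU​CCC​C-3′
NCKAP1	24	5′-CCG​GAG​ACG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCA​CAC​CUA​G-3′
RPRD2	24	5′-CCG​CUC​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCA​GAG​GAG​C-3′
UBTF	24	5′-CAG​CCA​CAG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCA​CAG​CAG​C-3′
TCEA1	24	5′-GAG​CCG​GAG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CGG​GCU​U-3′
THOC7	24	5′-CAG​CUU​GCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CGC​ACG​C-3′
USP7	24	5′-GGC​CGC​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCC​CGG​CUC​G-3′
ZNF219	24	5′-CGC​CGC​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCC​GCU​CCG​C-3′
SBF1	27–48	5′-ACC​UGG​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCG​GAG​CGA​ACC​AGG​GGU​GUC​CGG​GGT-3′
SMAD9	27–48	5′-GCU​GGG​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCU​GCU​GCA​GCC​GCU​GUC​UCG​GUC​CCC-3′
BCL11A	27–48	5′-CCG​CCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​CGC​CCC​GCA​GCC​CAC​CAU​GUC​TCG-3′
WBP4	27–48	5′-GCU​GCU​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCU​GCU​GCU​GCC​CAC​ACG​CUC​CCG-3′
GNB2	27–48	5′-AUC​CGC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​UCC​GCC​GCG​GAG​GAA​GAC-3′
KIF3B	27–48	5′-GCC​CCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​CGC​UUU​CGG​CUC​GGG​CCT-3′
NDRG3	27–48	5′-CCU​CUC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCU​GCU​GCU​GCA​CTG-3′
BCL2L11	27–48	5′-GCC​GCU​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​ACU​ACC​ACC​ACT-3′
RHOT1	27–48	5′-GAC​UCG​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​GCC​ACA​GCC-3′
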