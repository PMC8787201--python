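gene	block	sequence	peptide
ATOH8	18	5′-CUC​CCC​ACG​CCG​CCG​CCG​CCG​CCG​CCU​CCU​GCG​C-3′	PPPPPP
GABBR2	18	5′-CAG​CCC​GGG​CCG​CCG​CCG​CCG​CCG​CCA​CCG​CCG​C-3′	PPPPPP
FAM117B	18	5′-CCC​CCA​CGG​CCG​CCG​CCG​CCG​CCG​CCG​CUG​CUG​G-3′	PPPPPP
FOXG1	18	5′-CAG​CAG​CAG​CCG​CCG​CCG​CCG​CCG​CCC​CCG​GCA​C-3′	PPPPPP
FOXK1	18	5′-CCG​CCC​GGG​CCG​CCG​CCG​CCG​CCG​CCA​CCG​CCG​C-3′	PPPPPP
GPR150	18	5′-UCG​CCG​CUG​CCG​CCG​CCG​CCG​CCG​CCA​ACG​UCC​C-3′	PPPPPP
IRX5	18	5′-ACC​CCG​CGG​CCG​CCG​CCG​CCG​CCG​CCU​UCU​CCU​C-3′	PPPPPP
LOXL1	18	5′-CCC​UAC​GUG​CCG​CCG​CCG​CCG​CCG​CCC​CCC​GAC​G-3′	PPPPPP
LTBP1	18	5′-CUC​AGA​CCG​CCG​CCG​CCG​CCG​CCG​CCG​GAG​CCU​G-3′	RPPPPP
MECP2	18	5′-GGA​AAA​TGG​CCG​CCG​CCG​CCG​CCG​CCG​CGC​CGA​G-3′	PPPPPP
TMEM121	18	5′-AAC​UCG​GUG​CCG​CCG​CCG​CCG​CCG​CCG​CUG​CAC​G-3′	PPPPPP
TSPYL2	18	5′-CCG​CCC​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CUC​CUC​C-3′	PPPPPP
TPRN	18	5′-CGC​CCC​CCG​CCG​CCG​CCG​CCG​CCG​CCC​GCG​CCG​C-3′	PPPPPP
ZCCHC2	18	5′-CGC​CCC​CCG​CCG​CCG​CCG​CCG​CCG​CCC​GCG​GGC​C-3′	PPPPPP
ZNF367	18	5′-GAG​AAC​CCG​CCG​CCG​CCG​CCG​CCG​CCC​GUC​AUC​U-3′	PPPPPP
ZNF839	18	5′-AAG​GCG​CAG​CCG​CCG​CCG​CCG​CCG​CCC​CCC​UUC​G-3′	PPPPPP
FOXD1	18	5′-CGC​AGC​GCG​CCG​CCG​CCG​CCG​CCG​CCU​UCC​ACC​C-3′	AAAAAA
CASZ1	18	5′-GCG​AGG​GCG​CCG​CCG​CCG​CCG​CCG​CCG​CAG​CUG​G-3′	AAAAAA
GPR88	18	5′-CCG​GCU​GCG​CCG​CCG​CCG​CCG​CCG​CCU​UCC​CGG​G-3′	AAAAAA
FBXL17	18	5′-UAU​CCU​CGG​CCG​CCG​CCG​CCG​CCG​CCG​CUG​CCG​C-3′	AAAAAA
HOXA2	18	5′-UUC​UGC​CGG​CCG​CCG​CCG​CCG​CCG​CCA​CCG​CCG​C-3′	AAAAAA
HOXA13	18	5′-CCG​CUG​CAG​CCG​CCG​CCG​CCG​CCG​CCG​CGU​CGU​C-3′	AAAAAA
IRX2	18	5′-CGG​CCG​ACG​CCG​CCG​CCG​CCG​CCG​CCG​GCU​UCC​C-3′	AAAAAA
IRX3	18	5′-UCU​CUC​CGG​CCG​CCG​CCG​CCG​CCG​CCG​CUC​ACA​G-3′	AAAAAA
IRX4	18	5′-CAG​CCA​CCG​CCG​CCG​CCG​CCG​CCG​CCA​CCU​CCC​U-3′	AAAAAA
LCORL	18	5′-CCG​CUG​CUG​CCG​CCG​CCG​CCG​CCG​CCG​CUC​AGU​G-3′	AAAAAA
LHFPL3	18	5′-CCG​CCG​CUG​CCG​CCG​CCG​CCG​CCG​CCG​CGA​UGC​U-3′	AAAAAA
NANOS1	18	5′-GCG​CGC​CCG​CCG​CCG​CCG​CCG​CCG​CCA​CCA​CCA​C-3′	AAAAAA
POU3F3	18	5′-UGC​CCC​ACG​CCG​CCG​CCG​CCG​CCG​CCG​CUG​CCG​C-3′	AAAAAA
SOX12	18	5′-AGG​GGG​CGG​CCG​CCG​CCG​CCG​CCG​CCU​CCC​CGA​C-3′	AAAAAA
SOX21	18	5′-CCG​CCG​CUG​CCG​CCG​CCG​CCG​CCG​CCG​CGG​GCA​G-3′	AAAAAA
SP8	18	5′-GCG​CCG​CAG​CCG​CCG​CCG​CCG​CCG​CCG​CAG​CCG​C-3′	AAAAAA
UNCX	18	5′-CUU​CCA​ACG​CCG​CCG​CCG​CCG​CCG​CCG​CGG​GGC​U-3′	AAAAAA
ARX	21	5′-CGG​CCG​CUG​CCG​CCG​CCG​CCG​CCG​CCG​CCU​UCC​CGA​G-3′	AAAAAAA
DGKI	21	5′-CUC​CUG​CAG​CCG​CCG​CCG​CCG​CCG​CCG​CCA​GCC​CGC​C-3′	AAAAAAA
GSG1L	21	5′-CCG​CCC​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCA​CCG​CCU​C-3′	AAAAAAA
JUND	21	5′-CGG​CCG​CUG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​GGG​GGC​C-3′	AAAAAAA
SKOR2	21	5′-CCG​GCC​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCC​CCG​CCG​C-3′	PPPPPPP
CEBPA	21	5′-CCU​UAC​CAG​CCG​CCG​CCG​CCG​CCG​CCG​CCC​UCG​CAC​C-3′	PPPPPPP
CHD3	21	5′-CUC​UUC​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCA​CCG​CUG​C-3′	PPPPPPP
CTNND2	21	5′-GAG​CCC​GCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CGG​GAG​C-3′	PPPPPPP
HCN2	21	5′-GCG​CCG​GGG​CCG​CCG​CCG​CCG​CCG​CCG​CCC​GCG​CCC​C-3′	PPPPPPP
HTT	21	5′-CCG​CCA​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCU​CCU​CAG​C-3′	PPPPPPP
SOBP	21	5′-CCC​GAG​CAG​CCG​CCG​CCG​CCG​CCG​CCG​CCC​GCG​CCC​C-3′	PPPPPPP
TGFBR3L	21	5′-CCU​CUG​ACG​CCG​CCG​CCG​CCG​CCG​CCG​CCA​UCG​CGG​U-3′	PPPPPPP
SLC24A3	21	5′-CGC​GCG​UCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​GAG​GGA​C-3′	RRRRRRR
CCDC177	24	5′-GCC​CCG​CGG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CGG​CCU​C-3′	AAAAAAAA
IRS2	24	5′-AGC​CCA​GGG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​UGC​CUU​C-3′	AAAAAAAA
MEGF9	24	5′-UGU​GCU​GCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​UCG​CCU​C-3′	AAAAAAAA
SKIDA1	24	5′-ACC​CGG​CAG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CUG​CUG​C-3′	AAAAAAAA
ZIC3	24	5′-CAA​CCC​ACG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CUG​CCU​U-3′	AAAAAAAA
FMNL1	24	5′-GUG​CCU​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCU​CCC​GGA​G-3′	PPPPPPPP
GBX2	24	5′-GUA​GUG​CUG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCC​GCG​CUG​C-3′	PPPPPPPP
MMP24	24	5′-GCG​CCG​GGG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​GGC​CAG​G-3′	PPPPPPPP
TRIM67	24	5′-CUG​GUG​CAG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCC​GCC​GAG​G-3′	PPPPPPPP
DLX6	27–36	5′-CCT​GCC​CGG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CAG​CCG​CCT​CGC​AGC​A-3′	PPPPPPPPP
DMRTA2	27–36	5′-GCG​TCG​ACG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​GGG​GGC​CTG​GGC​TGC​C-3′	AAAAAAAAA
FOXF2	27–36	5′-CGC​CGC​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCC​CGG​AGA​CCA​CCT​CCT​C-3′	AAAAAAAAA
IRF2BPL	27–36	5′-TAA​GCG​CTG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CTG​CGG​TGG​AAC​AGC​G-3′	AAAAAAAAA
MNX1	27–36	5′-CGG​CCG​CTG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CTG​GGG​GCC​TGG​CGC​T-3′	AAAAAAAAA
NKX2-3	27–36	5′-CGG​CCG​CGG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CAG​CAG​CGG​CGG​CCT​A-3′	AAAAAAAAA
ZNF703	27–36	5′-TGG​GCA​GCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCT​CCT​GCC​ATC​TGC​ACC​T-3′	AAAAAAAAA
ZSWIM6	27–36	5′-CCG​CCG​CTG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CGG​GGG​CCG​GGG​C-3′	AAAAAAAAAA
CASKIN1	27–36	5′-CCC​CGC​GAG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CGC​CCC​CCG​CCC​C-3′	AAAAAAAAAA
FOXE1	27–36	5′-GCT​GCC​CAG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCA​TCT​TCC​CAG​G-3′	AAAAAAAAAAA
ZIC5	27–36	5′-GCC​GGG​CTG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCG​CCA​CCG​CCC​C-3′	PPPPPPPPPPP
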