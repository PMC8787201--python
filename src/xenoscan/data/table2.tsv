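gene	mirna_id	start	region	dG	ratio	length_nt	identical_human	milk
AR	bta-miR-2881	416	5UTR	-112	100	18	0	0
CXorf38	bta-miR-2444	1546	3UTR	-93	100	20	0	0
EGFR	bta-miR-11975	87	5UTR	-127	100	20	0	0
GLYCTK	bta-miR-135a	2812	3UTR	-113	100	23	1	1
LPPR5	bta-miR-151-5p	1328	3UTR	-113	100	21	1	0
LYPD3	bta-miR-151-5p	1608	3UTR	-113	100	21	1	0
MEX3A	bta-miR-1777b	301	CDS	-125	100	20	0	0
MEX3A	bta-miR-1777a	302	CDS	-123	100	20	0	0
PTP4A2	bta-miR-2444	2110	3UTR	-93	100	20	0	0
RBM43	bta-miR-2478	2911	3UTR	-106	100	20	0	0
RHOB	bta-miR-1777b	206	5UTR	-125	100	20	0	0
RTL1	bta-miR-136	110	CDS	-115	100	23	1	1
RTL1	bta-miR-432	330	CDS	-123	100	23	1	1
RTL1	bta-miR-127	1792	CDS	-121	100	22	1	1
RTL1	bta-miR-433	2878	CDS	-119	100	22	1	1
RTL1	bta-miR-431	3800	CDS	-127	100	23	1	1
SERF2	bta-miR-1282	1072	CDS	-102	100	20	1	0
ZIC5	bta-miR-11976	1316	CDS	-134	100	21	0	0
ZIC5	bta-miR-11975	1317	CDS	-127	100	20	0	0
ARID1A	bta-miR-1584-5p	4587	CDS	-115	98	20	0	0
ATP2B2	bta-miR-2444	7003	3UTR	-91	98	20	0	0
BCAM	bta-miR-6528	3012	3UTR	-108	98	20	0	0
CELF2	bta-miR-2444	5313	3UTR	-91	98	20	0	0
CTSH	bta-miR-2333	540	CDS	-117	98	21	0	0
HCN2	bta-miR-1777b	2374	CDS	-123	98	20	0	0
HDX	bta-miR-2444	5052	3UTR	-91	98	20	0	0
HOXB8	bta-miR-196a	1378	3UTR	-110	98	22	0	1
KLF9	bta-miR-2897	799	5UTR	-115	98	20	0	0
MCRS1	bta-miR-1584-5p	353	CDS	-115	98	20	0	0
RFNG	bta-miR-2412	1238	3UTR	-125	98	22	0	0
RGL2	bta-miR-10173-5p	310	5UTR	-117	98	22	0	0
RHOB	bta-miR-1777a	207	5UTR	-121	98	20	0	0
SEPT8	bta-miR-151-3p	2767	3UTR	-110	98	21	1	0
SLIT3	bta-miR-1584-5p	57	5UTR	-115	98	20	0	0
SPAM1	bta-miR-2285k	1320	CDS	-102	98	21	0	0
TAF4	bta-miR-1777b	763	CDS	-123	98	20	0	0
TMEM164	bta-miR-6528	2163	3UTR	-108	98	20	0	0
TNKS1BP1	bta-miR-6528	5595	3UTR	-108	98	20	0	0
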