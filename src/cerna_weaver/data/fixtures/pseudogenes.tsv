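pseudogene_id	pseudogene_locus	paralogue	accession	identity_pct	paralogue_chromosome
ENSCING00000018826	Scaffold HT000550.1: 1831-2416	Ubiquitin-conjugating enzyme E2 E1 (LOC100185453)	M_002129409.5	94.53	9
ENSCING00000015967	Scaffold HT000041.1: 63,841-64,434	E3 ubiquitin-protein ligase synoviolin A-like (LOC100182895)	XM_018814866.2	99.67	14
ENSCING00000001348	Scaffold HT000084.1: 79,125-80,530	PiggyBac transposable element-derived protein 4-like (LOC113475031)	XM_026838431.1	99.74	Unplaced Scaffold
ENSCING00000005443	Chromosome 1: 2,817,744-2,819,238	Katanin p60 ATPase-containing subunit A1-like (LOC100178737)	XM_009863895.3	99.67	1
ENSCING00000024145	Chromosome 14: 4,460,332-4,461,829	E3 ubiquitin-protein ligase synoviolin A-like (LOC100182895)	XM_018814866.2	99.67	14
ENSCING00000006910	Chromosome 9: 241,768-243,963	U3 small nucleolar RNA-associated protein 14 homolog A (LOC100182485)	XM_002119512.5	100.00	9
ENSCING00000024624	Chromosome 1: 9,732,896-9,735,685	Apoptosis-stimulating of p53 protein 1 (LOC100181784)	XM_002123552.5	100.00	1
ENSCING00000021320	Scaffold HT000124.1: 299,056-300,232	zinc finger protein (zf(c2h2)-32)	NM_001078404.1	98.98	Unplaced Scaffold
ENSCING00000015544	Scaffold HT000124.1: 300,647-301,709	zinc finger protein (zf(c2h2)-32)	NM_001078404.1	95.29	Unplaced Scaffold
ENSCING00000005867	Chromosome 2: 2,842,058-2,843,557	tRNA modification GTPase GTPBP3, mitochondrial (LOC100183076)	XM_002128700.5	98.20	2
ENSCING00000011392	Chromosome 2: 5,498,086-5,500,091	zinc finger protein (zf(c2h2)-31)	NM_001078403.1	98.80	2
ENSCING00000018962	Chromosome 4: 3,953,395-3,954,891	HSF protein (hsf)	NM_001078269.1	99.26	4
ENSCING00000000148	Scaffold HT000121.1: 61,799-64,445	Toll-like receptor 1 (ci-tlr1)	NM_001166127.2	100.00	Unplaced Scaffold
ENSCING00000008834	Chromosome 4: 4,639,472-4,640,938	FoxB protein (foxB)	NM_001032523.1	99.65	4
ENSCING00000001425	Scaffold HT000145.1: 8,837-11,898	Phosphatidylinositol 4,5-bisphosphate 3-kinase catalytic subunit alpha isoform-like (LOC100180252)	XM_004227228.4	99.80	Unplaced Scaffold
ENSCING00000007135	Chromosome 3: 220,836-221,952	Transcription factor protein (lag1-like3)	NM_001100125.1	99.37	3
ENSCING00000019275	Chromosome 11: 158,872-160,388	28S ribosomal protein S34, mitochondrial-like (LOC100182579), transcript variant X1	XM_002128752.5	99.87	11
ENSCING00000022279	Chromosome 3: 892,375-893,636	Aldehyde dehydrogenase, dimeric NADP-preferring-like (LOC100185488)	XM_009859599.3	99.76	3
ENSCING00000019638	Chromosome 13: 1,743,172-1,744,608	poly [ADP-ribose] polymerase 2 (LOC100178364)	XM_002128271.4	100.00	13
ENSCING00000009399	Chromosome 3: 3,711,873-3,713,223	major facilitator superfamily domain-containing protein 10-like (LOC100182178)	XM_009859732.3	99.85	3
ENSCING00000006160	Scaffold HT000098.1: 302,094-303,016	Not4 protein (not4)	NM_001032434.1	99.67	Unplaced Scaffold
ENSCING00000018651	Scaffold HT000098.1: 863,758-864,748	Uncharacterized LOC494370 (LOC494370), mRNA	NM_001245041.1	99.90	Unplaced Scaffold
ENSCING00000019488	Chromosome 11: 4,823,586-4,824,678	p38 kinase (p38)	NM_001078490.1	99.18	11
ENSCING00000008915	Chromosome 3: 5,548,986-5,553,157	DNA-directed RNA polymerase III subunit RPC1-like (LOC100185039)	XM_009859781.3	99.86	3
ENSCING00000001594	Scaffold HT000119.1: 138,999-140,115	Betaine-homocysteine S-methyltransferase 1 pseudogene (LOC104266620)	XR_001975199.2	99.91	Unplaced Scaffold
ENSCING00000007698	Chromosome 12: 2,614,369-2,618,285	RRP12-like protein (LOC100184722)	XM_009862261.3	99.92	12
ENSCING00000018747	Chromosome 8: 4,581,662-4,582,653	zinc finger protein (zf(c2h2)-21)	NM_001078395.1	99.70	8
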