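pathway	accession	gene_name	mirna	pseudogene
Wnt	NM_001078300	Nemo-Like kinase(Nemo-like)	cin-let-7d-5p
Wnt	NM_001078300	Nemo-Like kinase(Nemo-like)	cin-mir-4187-5p
Wnt	NM_001078300	Nemo-Like kinase(Nemo-like)	cin-mir-4011a-5p
Wnt	NM_001078476	Smad4 protein(Smad4)	cin-let-7d-5p
Wnt	NM_001078326	Wnt signaling ligand (LOC778720)	cin-mir-4056-3p
Wnt	NM_001078326	Wnt signaling ligand (LOC778720)	cin-mir-4150-5p
Wnt	NM_001078326	Wnt signaling ligand (LOC778720)	cin-mir-92c-5p	ENSCING00000011392
Wnt	NM_001032454	beta-transducin repeat-containing homologue protein(BetaTrCP)	cin-mir-4187-5p
Wnt	NM_001032425	glycogen synthase kinase alpha/beta(Gsk)	cin-mir-4189-5p	ENSCING00000018651
Wnt	NM_001032425	glycogen synthase kinase alpha/beta(Gsk)	cin-mir-4187-5p
Wnt	NM_001122968	prickle 2(Pk2)	cin-mir-4053-5p
Wnt	NM_001078496	secreted frizzled-related protein(Sfrp1/5)	cin-mir-153-5p	ENSCING00000007698
Wnt	NM_001078536	secreted frizzled-related protein(Sfrp2)	cin-mir-4011a-5p
Wnt	NM_001078536	secreted frizzled-related protein(Sfrp2)	cin-mir-4053-5p
Wnt	NM_001078528	transcription factor protein(Jun)	cin-mir-4056-5p
Wnt	NM_001078528	transcription factor protein(Jun)	cin-mir-4189-5p	ENSCING00000018651
Wnt	NM_001078528	transcription factor protein(Jun)	cin-mir-92c-5p	ENSCING00000011392
FoxO	NM_001078300	Nemo-Like kinase(Nemo-like)	cin-let-7d-5p
FoxO	NM_001078300	Nemo-Like kinase(Nemo-like)	cin-mir-4187-5p
FoxO	NM_001078300	Nemo-Like kinase(Nemo-like)	cin-mir-4011a-5p
FoxO	NM_001078349	Smad2/3b protein(Smad2/3b)	cin-mir-4011a-5p
FoxO	NM_001078476	Smad4 protein(Smad4)	cin-let-7d-5p
FoxO	NM_001078229	mitogen-activated protein kinase(Erk1/2)	cin-let-7d-5p
FoxO	NM_001078229	mitogen-activated protein kinase(Erk1/2)	cin-mir-4016
FoxO	NM_001078490	p38 kinase(P38)	cin-mir-4187-5p
FoxO	NM_001078490	p38 kinase(P38)	cin-mir-4053-5p
FoxO	NM_001078249	transcription factor protein(Foxo)	cin-mir-4053-5p
FoxO	NM_001078249	transcription factor protein(Foxo)	cin-mir-4150-5p
FoxO	NM_001078249	transcription factor protein(Foxo)	cin-mir-4011a-5p
FoxO	NM_001078368	transforming growth factor beta receptor(Tgfbr-iib)	cin-mir-4075-5p
FoxO	NM_001078368	transforming growth factor beta receptor(Tgfbr-iib)	cin-let-7d-5p
FoxO	NM_001078194	uncharacterized LOC778553(LOC778553)	cin-mir-4187-5p
Tgf-β	NM_001078349	Smad2/3b protein(Smad2/3b)	cin-mir-4011a-5p
Tgf-β	NM_001078476	Smad4 protein(Smad4)	cin-let-7d-5p
Tgf-β	NM_001078229	mitogen-activated protein kinase(Erk1/2)	cin-let-7d-5p
Tgf-β	NM_001078229	mitogen-activated protein kinase(Erk1/2)	cin-mir-4016
Tgf-β	NM_001078367	transforming growth factor beta receptor(Tgfbr-iia)	cin-mir-4187-5p
Tgf-β	NM_001078368	transforming growth factor beta receptor(Tgfbr-iib)	cin-let-7d-5p
Tgf-β	NM_001078196	transforming growth factor beta superfamily signaling ligand(Bmp5/7-like)	cin-let-7d-5p
Hh	NM_001032454	beta-transducin repeat-containing homologue protein(BetaTrCP)	cin-mir-4187-5p
Hh	NM_001032425	glycogen synthase kinase alpha/beta(Gsk)	cin-mir-4189-5p	ENSCING00000018651
Hh	NM_001032425	glycogen synthase kinase alpha/beta(Gsk)	cin-mir-4187-5p
Hh	NM_001078351	smoothened protein(Smoothened)	cin-let-7d-5p
Hh	NM_001078351	smoothened protein(Smoothened)	cin-mir-4183-5p
Hh	NM_001078483	transcription factor protein(Gli)	cin-mir-4187-5p
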