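biotype	count
protein_coding	6528
miRNA	90
pseudogene	27
snRNA	19
snoRNA	36
rRNA	11
miscRNA	10
mtRNA	8
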