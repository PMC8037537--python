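transcript_id	name
ENSCINT00000030081	cin-let-7a-2
ENSCINT00000030062	cin-let-7b
ENSCINT00000030060	cin-let-7c
ENSCINT00000030036	cin-let-7d
ENSCINT00000034599	cin-let-7f
ENSCINT00000030035	cin-mir-126
ENSCINT00000030087	cin-mir-141
ENSCINT00000030090	cin-mir-153
ENSCINT00000035589	cin-mir-375
ENSCINT00000030066	cin-mir-92a
ENSCINT00000030082	cin-mir-92c
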