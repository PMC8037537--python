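# Default 3'UTR cis-regulatory element patterns (IUPAC, RNA alphabet; U/T equivalent on load).
# Patterns are literature-standard consensi where one exists (ARE pentamer, CPE, MBE) and
# documented heuristics where the element is defined structurally (GAIT stem-loop: the loop
# consensus below is a heuristic and the hit additionally requires a flanking stem of at least
# min_stem complementary base pairs within a 30-nt window).  The table is editable; scans are
# always reported against whatever patterns are loaded.
name	pattern	requires_hairpin	min_stem	note
MBE	RUAGU	false	0	musashi-binding element core consensus
GAIT	GAAUCCC	true	5	gamma-interferon-activated inhibitor of translation; heuristic loop consensus, stem required
CPE	UUUUWAU	false	0	cytoplasmic polyadenylation element (UUUUUAU with UUUUAAU variant)
ARE	AUUUA	false	0	AU-rich destabilization pentamer
MOS-PRE	AUUUUAAU	false	0	polyadenylation response element, heuristic consensus
GU-rich	UGUUUGUUUGU	false	0	GU-rich destabilization element (UGU repeats)
UNR	AAGUA	false	0	UNR (cold-shock domain RNA-binding protein) site core, heuristic
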