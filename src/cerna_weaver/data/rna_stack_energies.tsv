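# Nearest-neighbor helix stacking free energies for RNA/RNA duplexes, kcal/mol at 37 C.
# Turner-style Watson-Crick values; GU-wobble steps use commonly cited magnitudes, with the
# weakly destabilizing wobble-wobble steps clamped to small negative values so that every
# stack in the model is <= 0 (the bulge/initiation terms carry all destabilization).
# A step is written as two base pairs (5'->3' on the miRNA strand): pair1<TAB>pair2<TAB>dG.
# Each pair is "XY" = miRNA base X paired with target base Y.  Entries not listed are filled
# by the strand-flip symmetry (p1,p2) == (reverse(p2), reverse(p1)).
pair1	pair2	dG
AU	AU	-0.93
AU	UA	-1.10
UA	AU	-1.33
CG	UA	-2.08
CG	AU	-2.11
GC	UA	-2.24
GC	AU	-2.35
CG	GC	-2.36
GC	GC	-3.26
GC	CG	-3.42
AU	GU	-0.55
AU	UG	-1.36
UA	GU	-1.27
UA	UG	-1.00
CG	GU	-1.41
CG	UG	-2.11
GC	GU	-1.53
GC	UG	-2.51
GU	GU	-0.50
GU	UG	-0.20
UG	GU	-0.30
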