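"""Scan 3'UTRs for cis-regulatory elements (ARE, CPE, MBE, GAIT, ...).

Scans a hand-built UTR containing an AU-rich destabilization pentamer, a
cytoplasmic polyadenylation element and a GAIT stem-loop, then prints the
presence/absence profile.
"""

from cerna_weaver import default_motif_table, element_profile, scan_utr
from cerna_weaver.sequences import revcomp

stem = "GCAGGC"
utr = ("GCGCGC" + "AUUUA"            # ARE
       + "GGCGG" + "UUUUUAU"         # CPE
       + "CACA" + stem + "GAAUCCC" + revcomp(stem)  # GAIT loop inside a stem
       + "GCGCGC")
hits = scan_utr(utr, transcript_id="demo")
for h in hits:
    print(f"{h.element:8s} {h.start:3d}-{h.end:<3d} {h.match}")

profile = element_profile({"demo": hits}, ["demo"])
print("\npresence/absence profile (True = at least one hit):")
print(profile.to_string())
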