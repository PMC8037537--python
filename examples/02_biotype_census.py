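"""Tally transcripts by biotype and summarize the coding/noncoding breakdown.

Uses the packaged census table of the Ciona robusta pharynx transcriptome:
6729 annotated transcripts of which 201 are noncoding RNAs (miRNAs,
pseudogenes, snRNAs, snoRNAs, rRNAs, miscRNAs, mtRNAs).
"""

from cerna_weaver import classify_biotypes, load_fixture

census = classify_biotypes(load_fixture("biotype_counts"))
print(census.to_frame().to_string(index=False))
print(f"\ntotal {census.total}, noncoding {census.noncoding_total} "
      f"({census.fraction_noncoding:.1%} of annotated transcripts)")
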