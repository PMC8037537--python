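"""Generate a small synthetic transcriptome with planted ground truth.

Builds 10 mRNAs, 5 miRNAs and 3 pseudogenes, and shows what the generator
records: every planted miRNA response element (a perfect seed complement in a
3'UTR) and every pseudogene's realized identity to its parent.
"""

from cerna_weaver import SynthConfig, gen_transcriptome

cfg = SynthConfig(n_mrna=10, n_mirna=5, n_pseudogene=3, rng_seed=1)
transcripts, mirnas, truth = gen_transcriptome(cfg)

print(f"{len(transcripts)} transcripts ({len(mirnas)} miRNA precursors among them)")
print("\nfirst planted sites (miRNA, target, 1-based site on the transcript):")
for mirna_id, target_id, start, end in truth.planted_interactions[:5]:
    print(f"  {mirna_id} -> {target_id} at {start}-{end}")
print("\npseudogene identities to their parents (the generator aims for 94-100%):")
for pid, parent, identity in truth.pseudogene_parents:
    print(f"  {pid} from {parent}: {identity:.4f}")
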