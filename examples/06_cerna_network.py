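"""Build the ceRNA network from the packaged pathway interaction table.

Overlays the retained miRNA-mRNA and miRNA-pseudogene interactions of the
Wnt, FoxO, Tgf-beta and Hedgehog pathways, lists the miRNA/pseudogene
competing couples, and the proteins shared by two or more pathways.
"""

from cerna_weaver import build_network, cerna_couples, shared_proteins
from cerna_weaver.ceweb import fixture_interactions, fixture_pathway_sets, gene_display_names

sets = fixture_pathway_sets()
graph = build_network(fixture_interactions(), sets)
names = gene_display_names()

print(f"network: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges "
      f"across pathways {sorted(sets)}")

print("\nceRNA couples (a pseudogene competing with pathway genes for one miRNA):")
for c in cerna_couples(graph):
    genes = ", ".join(names.get(g, g) for g in c.gene_ids)
    print(f"  {c.mirna_id} <-> {c.pseudogene_id}  [{'/'.join(c.pathways)}]  genes: {genes}")

print("\nproteins shared by >= 2 pathways:")
for gene, pws in sorted(shared_proteins(sets).items()):
    print(f"  {names.get(gene, gene)}: {', '.join(sorted(pws))}")
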