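"""ceRNA network construction: typed graph, couples, shared proteins, export.

The graph has typed nodes (gene, miRNA, pseudogene, pathway) and typed edges:
``targets`` (miRNA -> gene), ``sequesters`` (miRNA -> pseudogene; the
pseudogene competes for the miRNA) and ``member_of`` (gene -> pathway).  A
ceRNA couple is a (miRNA, pseudogene) pair connected by a sequesters edge
whose miRNA also targets at least one pathway gene: the pseudogene can then
titrate the miRNA away from those genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .census import load_fixture
from .errors import ValidationError
from .records import DuplexInteraction

EDGE_TYPES = {"targets", "sequesters", "member_of"}


@dataclass(frozen=True)
class CeRNACouple:
    """One miRNA/pseudogene competing pair with the genes and pathways it touches."""

    mirna_id: str
    pseudogene_id: str
    gene_ids: tuple[str, ...]
    pathways: tuple[str, ...]


def build_network(
    interactions: Iterable[DuplexInteraction],
    pathway_sets: Mapping[str, Iterable[str]],
) -> nx.DiGraph:
    """Overlay filtered interactions on pathway gene sets.

    Gene-targeting interactions enter only when the gene belongs to at least
    one supplied pathway; pseudogene interactions enter whenever their miRNA
    was retained (targets >= 1 pathway gene).  Duplicate (miRNA, target) rows
    collapse to one edge keeping the minimum deltaG.  All pathway genes get
    nodes and member_of edges regardless of interactions.
    """
    pathways = {p: sorted(set(genes)) for p, genes in pathway_sets.items()}
    gene_pathways: dict[str, set[str]] = {}
    for p, genes in pathways.items():
        for g in genes:
            gene_pathways.setdefault(g, set()).add(p)

    g_edges: dict[tuple[str, str], float] = {}
    p_edges: dict[tuple[str, str], float] = {}
    mirna_retained: set[str] = set()
    pseudo_rows = []
    for it in interactions:
        if it.target_kind == "pseudogene":
            pseudo_rows.append(it)
        elif it.target_id in gene_pathways:
            key = (it.mirna_id, it.target_id)
            if key not in g_edges or it.delta_g < g_edges[key]:
                g_edges[key] = it.delta_g
            mirna_retained.add(it.mirna_id)
    for it in pseudo_rows:
        if it.mirna_id in mirna_retained:
            key = (it.mirna_id, it.target_id)
            if key not in p_edges or it.delta_g < p_edges[key]:
                p_edges[key] = it.delta_g

    G = nx.DiGraph()
    for p in sorted(pathways):
        G.add_node(p, kind="pathway")
    for gene in sorted(gene_pathways):
        G.add_node(gene, kind="gene")
    for m in sorted({m for m, _ in g_edges} | {m for m, _ in p_edges}):
        G.add_node(m, kind="miRNA")
    for ps in sorted({t for _, t in p_edges}):
        G.add_node(ps, kind="pseudogene")
    for gene in sorted(gene_pathways):
        for p in sorted(gene_pathways[gene]):
            G.add_edge(gene, p, edge_type="member_of")
    for (m, gene), dg in sorted(g_edges.items()):
        G.add_edge(m, gene, edge_type="targets", delta_g=float(dg))
    for (m, ps), dg in sorted(p_edges.items()):
        G.add_edge(m, ps, edge_type="sequesters", delta_g=float(dg))
    return G


def cerna_couples(graph: nx.DiGraph) -> list[CeRNACouple]:
    """All (miRNA, pseudogene) couples, sorted by miRNA then pseudogene id."""
    couples = []
    for u, v, data in graph.edges(data=True):
        if data.get("edge_type") != "sequesters":
            continue
        genes = sorted(
            w for _, w, d in graph.out_edges(u, data=True) if d.get("edge_type") == "targets"
        )
        if not genes:
            continue
        pathways = sorted(
            {
                p
                for g in genes
                for _, p, d in graph.out_edges(g, data=True)
                if d.get("edge_type") == "member_of"
            }
        )
        couples.append(CeRNACouple(u, v, tuple(genes), tuple(pathways)))
    return sorted(couples, key=lambda c: (c.mirna_id, c.pseudogene_id))


def shared_proteins(pathway_sets: Mapping[str, Iterable[str]]) -> dict[str, set[str]]:
    """Genes annotated to two or more pathways -> the set of pathways sharing them."""
    membership: dict[str, set[str]] = {}
    for p, genes in pathway_sets.items():
        for g in set(genes):
            membership.setdefault(g, set()).add(p)
    return {g: ps for g, ps in membership.items() if len(ps) >= 2}


def export_graph(graph: nx.DiGraph, path: str | Path, fmt: str = "tsv") -> Path:
    """Write the graph as an edge-list TSV or GraphML; round-trip safe."""
    path = Path(path)
    canon = _canonical(graph)
    if fmt == "tsv":
        rows = [
            {
                "source": u,
                "target": v,
                "source_kind": canon.nodes[u]["kind"],
                "target_kind": canon.nodes[v]["kind"],
                "edge_type": d["edge_type"],
                "delta_g": d.get("delta_g", ""),
            }
            for u, v, d in canon.edges(data=True)
        ]
        pd.DataFrame(
            rows, columns=["source", "target", "source_kind", "target_kind", "edge_type", "delta_g"]
        ).to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        nx.write_graphml(canon, path, named_key_ids=True)
    else:
        raise ValidationError(f"unknown export format {fmt!r}")
    return path


def import_graph(path: str | Path, fmt: str = "tsv") -> nx.DiGraph:
    """Re-read an exported graph (inverse of :func:`export_graph`)."""
    path = Path(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        G = nx.DiGraph()
        for row in df.itertuples(index=False):
            G.add_node(row.source, kind=row.source_kind)
            G.add_node(row.target, kind=row.target_kind)
            attrs = {"edge_type": row.edge_type}
            if row.delta_g != "":
                attrs["delta_g"] = float(row.delta_g)
            G.add_edge(row.source, row.target, **attrs)
        return G
    if fmt == "graphml":
        return nx.DiGraph(nx.read_graphml(path))
    raise ValidationError(f"unknown import format {fmt!r}")


def _canonical(graph: nx.DiGraph) -> nx.DiGraph:
    """Deterministically ordered copy (sorted nodes, then sorted edges)."""
    G = nx.DiGraph()
    for n in sorted(graph.nodes):
        G.add_node(n, **graph.nodes[n])
    for u, v in sorted(graph.edges):
        G.add_edge(u, v, **graph.edges[u, v])
    return G


# ---------------------------------------------------------------------------
# reference-table fixture adapters

def fixture_pathway_sets() -> dict[str, list[str]]:
    """Pathway -> gene accessions from the packaged interaction table."""
    df = load_fixture("pathway_interactions")
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.pathway, [])
        if row.accession not in out[row.pathway]:
            out[row.pathway].append(row.accession)
    return out


def fixture_interactions() -> list[DuplexInteraction]:
    """The packaged interaction table as DuplexInteraction records.

    The table carries no coordinates or energies (it is a summary of retained
    interactions), so placeholder site (1, 7) and deltaG just under the -12
    filter are used; graph construction only consumes ids and kinds.
    """
    df = load_fixture("pathway_interactions")
    out = []
    seen = set()
    for row in df.itertuples(index=False):
        key = (row.mirna, row.accession)
        if key not in seen:
            seen.add(key)
            out.append(DuplexInteraction(row.mirna, row.accession, "mRNA", 1, 7, 0.0, -12.01))
        if row.pseudogene:
            pkey = (row.mirna, row.pseudogene)
            if pkey not in seen:
                seen.add(pkey)
                out.append(
                    DuplexInteraction(row.mirna, row.pseudogene, "pseudogene", 1, 7, 0.0, -12.01)
                )
    return out


def gene_display_names() -> dict[str, str]:
    """Accession -> printed gene name from the packaged interaction table."""
    df = load_fixture("pathway_interactions")
    return {row.accession: row.gene_name for row in df.itertuples(index=False)}
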