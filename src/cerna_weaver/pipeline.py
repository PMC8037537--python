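"""End-to-end orchestration: config validation, staged runs, manifest, report.

Two run modes exist.  ``synth`` generates a seeded synthetic transcriptome and
pushes it through every stage (census, precursor annotation, target
prediction for mRNAs and pseudogenes, enrichment, 3'UTR element scan, ceRNA
network); ``fixtures`` analyses the packaged reference tables (miRNA
catalogues, pseudogene identities, pathway interaction network).  Every run
writes TSV sidecars, a Markdown report and a JSON manifest with the config
snapshot, seeds, per-stage record counts and sha256 digests of all outputs;
re-running with the same config reproduces identical digests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__, ceweb, enrich, mircat, synthgen, targetpred, utr3scan
from .census import classify_biotypes, load_fixture
from .errors import ConfigurationError
from .synthgen import SynthConfig

DEFAULT_CONFIG: dict[str, Any] = {
    "mode": "synth",
    "seed": 0,
    "n_mrna": 100,
    "n_mirna": 20,
    "n_pseudogene": 10,
    "utr_len_range": [150, 300],
    "cds_len_range": [150, 450],
    "mature_len": 22,
    "precursor_loop_len": 15,
    "identity_range": [0.94, 1.0],
    "planted_sites_per_utr": 1,
    "tail_complementarity": 0.7,
    "planted_elements": ["MBE", "GAIT", "CPE", "ARE", "MOS-PRE", "GU-rich", "UNR"],
    "dg_cut": -12.0,
    "tau": 0.3,
    "max_bulge": 4,
    "e_cut": 1e-5,
    "p_cut": 0.05,
    "q_cut": 0.05,
    "ease_cut": 0.1,
    "n_terms": 15,
    "n_pathways": 4,
}


def validate_config(config: Mapping[str, Any] | None) -> dict[str, Any]:
    """Fill defaults, reject unknown keys and out-of-range values; idempotent."""
    config = dict(config or {})
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**DEFAULT_CONFIG, **config}
    if cfg["mode"] not in {"synth", "fixtures"}:
        raise ConfigurationError(f"unknown mode {cfg['mode']!r}")
    if cfg["dg_cut"] >= 0:
        raise ConfigurationError("dg_cut must be negative (kcal/mol)")
    if not (0 < cfg["e_cut"]):
        raise ConfigurationError("e_cut must be positive")
    for key in ("p_cut", "q_cut", "ease_cut"):
        if not (0 < cfg[key] <= 1):
            raise ConfigurationError(f"{key} must lie in (0, 1]")
    if not (0 <= cfg["tau"] <= 1):
        raise ConfigurationError("tau must lie in [0, 1]")
    for key in ("utr_len_range", "cds_len_range", "identity_range"):
        cfg[key] = [*map(float, cfg[key])] if key == "identity_range" else [*map(int, cfg[key])]
        if len(cfg[key]) != 2 or cfg[key][0] > cfg[key][1]:
            raise ConfigurationError(f"{key} must be a [lo, hi] pair")
    cfg["planted_elements"] = [str(e) for e in cfg["planted_elements"]]
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _synth_config(cfg: Mapping[str, Any]) -> SynthConfig:
    return SynthConfig(
        n_mrna=cfg["n_mrna"],
        n_mirna=cfg["n_mirna"],
        n_pseudogene=cfg["n_pseudogene"],
        utr_len_range=tuple(cfg["utr_len_range"]),
        cds_len_range=tuple(cfg["cds_len_range"]),
        mature_len=cfg["mature_len"],
        precursor_loop_len=cfg["precursor_loop_len"],
        identity_range=tuple(cfg["identity_range"]),
        planted_sites_per_utr=cfg["planted_sites_per_utr"],
        tail_complementarity=cfg["tail_complementarity"],
        planted_elements=tuple(cfg["planted_elements"]),
        rng_seed=cfg["seed"],
    )


def run_all(config: Mapping[str, Any] | None, out_dir: str | Path) -> dict[str, Any]:
    """Run every stage for the configured mode; returns the manifest."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg["mode"] == "synth":
        manifest = _run_synth(cfg, out)
    else:
        manifest = _run_fixtures(cfg, out)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _run_synth(cfg: dict[str, Any], out: Path) -> dict[str, Any]:
    counts: dict[str, Any] = {}
    report: list[str] = ["# cerna-weaver synthetic run", ""]

    # stage 1: generate
    transcripts, mirnas, truth = synthgen.gen_transcriptome(_synth_config(cfg))
    paths = synthgen.write_bundle(transcripts, mirnas, truth, out)
    counts["transcripts"] = len(transcripts)
    counts["mirnas"] = len(mirnas)
    counts["planted_interactions"] = len(truth.planted_interactions)
    counts["planted_elements"] = len(truth.planted_elements)

    # stage 2: census
    census = classify_biotypes(synthgen.annotation_frame(transcripts))
    census.to_frame().to_csv(out / "census.tsv", sep="\t", index=False)
    counts["census_total"] = census.total
    report += [
        "## Biotype census",
        "",
        f"{census.total} transcripts, {census.noncoding_total} noncoding "
        f"({census.fraction_noncoding:.1%}).",
        "",
    ]

    # stage 3: precursor annotation
    ann = mircat.annotate_precursors(
        [(m.id, m.precursor) for m in mirnas],
        [(m.id, m.mature) for m in mirnas],
        e_cut=cfg["e_cut"],
    )
    ann.to_csv(out / "precursor_annotation.tsv", sep="\t", index=False)
    recovered = int((ann["accepted"] & (ann["query_id"] == ann["subject_id"])).sum())
    counts["precursors_annotated"] = int(ann["accepted"].sum())
    counts["precursors_recovered"] = recovered
    report += [
        "## Precursor annotation",
        "",
        f"{recovered}/{len(mirnas)} precursors annotated to their own mature "
        f"(E-value cut {cfg['e_cut']:g}).",
        "",
    ]

    # stage 4: target prediction (separate mRNA and pseudogene runs)
    params = targetpred.PredictParams(
        tau=cfg["tau"], dg_cut=cfg["dg_cut"], max_bulge=cfg["max_bulge"], som_seed=cfg["seed"]
    )
    mrnas = [t for t in transcripts if t.biotype == "protein_coding"]
    pseudos = [t for t in transcripts if t.biotype == "pseudogene"]
    inter_m, stats_m = targetpred.predict(mirnas, mrnas, params)
    inter_p, stats_p = targetpred.predict(mirnas, pseudos, params)
    targetpred.interactions_frame(inter_m).to_csv(out / "interactions_mrna.tsv", sep="\t", index=False)
    targetpred.interactions_frame(inter_p).to_csv(
        out / "interactions_pseudogene.tsv", sep="\t", index=False
    )
    counts["mrna_candidates"] = stats_m.candidates
    counts["mrna_passed_tau"] = stats_m.passed_tau
    counts["mrna_interactions"] = len(inter_m)
    counts["pseudogene_interactions"] = len(inter_p)
    truth_pairs = {(m, t) for m, t, _, _ in truth.planted_interactions}
    pred_pairs = {(x.mirna_id, x.target_id) for x in inter_m}
    sens = len(truth_pairs & pred_pairs) / len(truth_pairs) if truth_pairs else 0.0
    counts["planted_site_sensitivity"] = round(sens, 4)
    report += [
        "## Target prediction",
        "",
        f"mRNA run: {stats_m.candidates} candidates, {stats_m.passed_tau} past the "
        f"dissimilarity gate (tau={cfg['tau']}), {len(inter_m)} interactions with "
        f"deltaG < {cfg['dg_cut']} kcal/mol.",
        f"Pseudogene run: {len(inter_p)} interactions.",
        f"Planted-site sensitivity: {sens:.3f}.",
        "",
    ]

    # stage 5: enrichment on predicted target genes
    population = [t.id for t in mrnas]
    study = sorted({x.target_id for x in inter_m})
    term_map = enrich.synthetic_term_map(
        population, n_terms=cfg["n_terms"], rng_seed=cfg["seed"] + 1
    )
    rows = enrich.fisher_enrich(study, population, term_map)
    rows.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    sig = enrich.filter_significant(rows, cfg["p_cut"], cfg["q_cut"], cfg["ease_cut"])
    counts["enrichment_terms"] = len(rows)
    counts["enrichment_significant"] = len(sig)
    report += [
        "## Enrichment",
        "",
        f"{len(rows)} terms tested, {len(sig)} significant at p<{cfg['p_cut']}, "
        f"Benjamini<{cfg['q_cut']}, EASE<={cfg['ease_cut']}.",
        "",
    ]

    # stage 6: 3'UTR element scan
    table = utr3scan.default_motif_table()
    hits_by_tx = {t.id: utr3scan.scan_utr(t.utr3_seq, table, transcript_id=t.id) for t in mrnas}
    all_hits = [h for hits in hits_by_tx.values() for h in hits]
    utr3scan.hits_frame(all_hits).to_csv(out / "utr_hits.tsv", sep="\t", index=False)
    profile = utr3scan.element_profile(hits_by_tx, [t.id for t in mrnas], table)
    profile.to_csv(out / "utr_profile.tsv", sep="\t")
    # element recovery vs truth (hits are UTR-relative here, truth is absolute)
    utr_off = {t.id: t.utr3[0] - 1 for t in mrnas}
    found = {
        (tid, h.element, h.start + utr_off[tid], h.end + utr_off[tid])
        for tid, hits in hits_by_tx.items()
        for h in hits
    }
    n_rec = sum((tid, el, s, e) in found for tid, el, s, e in truth.planted_elements)
    counts["utr_hits"] = len(all_hits)
    counts["planted_elements_recovered"] = n_rec
    report += [
        "## 3'UTR elements",
        "",
        f"{len(all_hits)} hits across {len(mrnas)} UTRs; "
        f"{n_rec}/{len(truth.planted_elements)} planted elements recovered at truth coordinates.",
        "",
    ]

    # stage 7: ceRNA network over synthetic pathway sets
    pathway_map = enrich.synthetic_term_map(
        population, n_terms=cfg["n_pathways"], size_range=(15, 40), rng_seed=cfg["seed"] + 2
    )
    pathway_sets = {f"PW{i + 1}": genes for i, (_, genes) in enumerate(sorted(pathway_map.items()))}
    graph = ceweb.build_network(inter_m + inter_p, pathway_sets)
    couples = ceweb.cerna_couples(graph)
    ceweb.export_graph(graph, out / "network.tsv", "tsv")
    ceweb.export_graph(graph, out / "network.graphml", "graphml")
    counts["network_nodes"] = graph.number_of_nodes()
    counts["network_edges"] = graph.number_of_edges()
    counts["cerna_couples"] = len(couples)
    report += [
        "## ceRNA network",
        "",
        f"{graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges, "
        f"{len(couples)} miRNA-pseudogene couples.",
        "",
    ]

    (out / "report.md").write_text("\n".join(report))
    files = sorted(p.name for p in out.iterdir() if p.suffix in {".tsv", ".md", ".fasta", ".graphml"})
    return {
        "version": __version__,
        "mode": "synth",
        "config": cfg,
        "seeds": {"rng_seed": cfg["seed"], "som_seed": cfg["seed"]},
        "counts": counts,
        "digests": {name: _digest(out / name) for name in files},
    }


def _run_fixtures(cfg: dict[str, Any], out: Path) -> dict[str, Any]:
    counts: dict[str, Any] = {}
    report: list[str] = ["# cerna-weaver fixture run", ""]

    census = classify_biotypes(load_fixture("biotype_counts"))
    census.to_frame().to_csv(out / "census.tsv", sep="\t", index=False)
    counts["census_total"] = census.total
    counts["census_noncoding"] = census.noncoding_total
    report += [
        "## Biotype census",
        "",
        f"{census.total} annotated transcripts, {census.noncoding_total} noncoding.",
        "",
    ]

    conserved = load_fixture("conserved_mirnas")
    specific = load_fixture("specific_mirnas")
    counts["conserved_mirnas"] = len(conserved)
    counts["specific_mirnas"] = len(specific)

    pseudo = load_fixture("pseudogenes")
    counts["pseudogenes"] = len(pseudo)
    counts["pseudogene_identity_min"] = float(pseudo["identity_pct"].min())
    counts["pseudogene_identity_max"] = float(pseudo["identity_pct"].max())

    pathway_sets = ceweb.fixture_pathway_sets()
    graph = ceweb.build_network(ceweb.fixture_interactions(), pathway_sets)
    couples = ceweb.cerna_couples(graph)
    shared = ceweb.shared_proteins(pathway_sets)
    ceweb.export_graph(graph, out / "network.tsv", "tsv")
    ceweb.export_graph(graph, out / "network.graphml", "graphml")
    pd.DataFrame(
        [
            {
                "mirna_id": c.mirna_id,
                "pseudogene_id": c.pseudogene_id,
                "genes": ";".join(c.gene_ids),
                "pathways": ";".join(c.pathways),
            }
            for c in couples
        ]
    ).to_csv(out / "couples.tsv", sep="\t", index=False)
    pathways = sorted(pathway_sets)
    counts["pathways"] = len(pathways)
    counts["cerna_couples"] = len(couples)
    counts["shared_proteins"] = len(shared)
    counts["network_pseudogenes"] = sum(
        1 for _, d in graph.nodes(data=True) if d["kind"] == "pseudogene"
    )
    names = ceweb.gene_display_names()
    report += [
        "## ceRNA network",
        "",
        "Pathways: " + ", ".join(pathways),
        f"{len(couples)} miRNA-pseudogene couples; {len(shared)} proteins shared by >=2 pathways.",
        "",
        "### Couples",
        "",
    ]
    for c in couples:
        genes = ", ".join(names.get(g, g) for g in c.gene_ids)
        report.append(f"- {c.mirna_id} <-> {c.pseudogene_id} (genes: {genes})")
    report.append("")

    (out / "report.md").write_text("\n".join(report))
    files = sorted(p.name for p in out.iterdir() if p.suffix in {".tsv", ".md", ".graphml"})
    return {
        "version": __version__,
        "mode": "fixtures",
        "config": cfg,
        "pathways": pathways,
        "counts": counts,
        "digests": {name: _digest(out / name) for name in files},
    }
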