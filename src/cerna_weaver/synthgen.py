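"""Synthetic transcriptome generator with planted ground truth.

The generator emulates the input classes the downstream analysis expects from
an annotated transcriptome: protein-coding transcripts whose 3'UTRs carry
planted miRNA response elements (MREs) and cis-regulatory elements, hairpin
miRNA precursors embedding their mature sequences, and pseudogenes produced as
high-identity (94-100%) mutated copies of parent mRNAs.  Everything planted is
recorded in a :class:`TruthTable` so recovery can be scored exactly.

A planted MRE is a perfect reverse complement of the planting miRNA's 7-nt
seed, preceded (5'-ward, so that the mature:site duplex is one antiparallel
helix) by a tail-complement block whose identity to the perfect complement is
controlled by ``tail_complementarity`` (default 70%); this gives the duplex
free-energy filter signal to separate planted sites from background.
Background sequence is i.i.d. uniform over ACGU unless a composition vector is
configured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .records import MiRNARecord, TranscriptRecord, seed_of
from .sequences import IUPAC, RNA_ALPHABET, require_rna, revcomp, write_fasta

_BASES = np.array(list(RNA_ALPHABET))


@dataclass
class SynthConfig:
    """Study conditions for one synthetic transcriptome."""

    n_mrna: int = 100
    n_mirna: int = 20
    n_pseudogene: int = 10
    utr_len_range: tuple[int, int] = (100, 300)
    cds_len_range: tuple[int, int] = (150, 450)
    mature_len: int = 22
    precursor_loop_len: int = 15
    identity_range: tuple[float, float] = (0.94, 1.00)
    planted_sites_per_utr: int | tuple[int, int] = 1
    tail_complementarity: float = 0.7
    planted_elements: tuple[str, ...] = ()
    background_composition: tuple[float, float, float, float] | None = None
    rng_seed: int = 0

    def validate(self) -> "SynthConfig":
        if min(self.n_mrna, self.n_mirna, self.n_pseudogene) < 0:
            raise ConfigurationError("counts must be >= 0")
        lo, hi = self.identity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError(f"identity_range {self.identity_range} not within [0, 1]")
        ulo, uhi = self.utr_len_range
        if not (7 <= ulo <= uhi):
            raise ConfigurationError("utr_len_range min must be >= seed length (7)")
        if not (18 <= self.mature_len <= 25):
            raise ConfigurationError("mature_len must be within 18-25 nt")
        if self.n_pseudogene > 0 and self.n_mrna == 0:
            raise ConfigurationError("pseudogenes need parent mRNAs")
        if not (0.0 <= self.tail_complementarity <= 1.0):
            raise ConfigurationError("tail_complementarity must be within [0, 1]")
        if self.background_composition is not None:
            comp = np.asarray(self.background_composition, dtype=float)
            if comp.shape != (4,) or (comp < 0).any() or not np.isclose(comp.sum(), 1.0):
                raise ConfigurationError("background_composition must be 4 probabilities summing to 1")
        return self


@dataclass
class TruthTable:
    """Coordinates of everything the generator planted (1-based closed intervals)."""

    planted_interactions: list[tuple[str, str, int, int]] = field(default_factory=list)
    planted_elements: list[tuple[str, str, int, int]] = field(default_factory=list)
    pseudogene_parents: list[tuple[str, str, float]] = field(default_factory=list)

    def interactions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.planted_interactions, columns=["mirna_id", "target_id", "site_start", "site_end"]
        )

    def elements_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.planted_elements, columns=["transcript_id", "element", "start", "end"]
        )

    def pseudogenes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pseudogene_parents, columns=["pseudogene_id", "parent_id", "realized_identity"]
        )


def _random_seq(rng: np.random.Generator, length: int, comp=None) -> str:
    if length <= 0:
        return ""
    idx = rng.choice(4, size=length, p=comp)
    return "".join(_BASES[idx])


def mutate_copy(seq: str, identity_target: float, rng: np.random.Generator) -> str:
    """Substitution-only mutated copy realizing exactly round(len*identity)/len identity."""
    if not (0.0 <= identity_target <= 1.0):
        raise ValidationError("identity_target must be within [0, 1]")
    s = list(require_rna(seq))
    n = len(s)
    n_mut = n - round(n * identity_target)
    if n_mut == 0:
        return "".join(s)
    positions = rng.choice(n, size=n_mut, replace=False)
    for p in positions:
        alternatives = [b for b in RNA_ALPHABET if b != s[p]]
        s[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(s)


def make_hairpin(mature: str, loop_len: int, rng: np.random.Generator) -> str:
    """Precursor hairpin: mature + loop + near-reverse-complement 3' arm.

    The 3' arm is the reverse complement of the mature with up to 3 random
    mismatches.  Total length must land in the 59-77 nt precursor band.
    """
    m = require_rna(mature, what="mature")
    if not (18 <= len(m) <= 25):
        raise ConfigurationError(f"mature length {len(m)} outside 18-25 nt")
    if loop_len < 1:
        raise ConfigurationError("loop length must be >= 1")
    total = 2 * len(m) + loop_len
    if not (59 <= total <= 77):
        raise ConfigurationError(f"precursor length {total} outside the 59-77 nt band")
    loop = _random_seq(rng, loop_len)
    arm = list(revcomp(m))
    n_mm = int(rng.integers(0, 4))  # 0..3 mismatches on the 3' arm
    if n_mm:
        for p in rng.choice(len(arm), size=n_mm, replace=False):
            alternatives = [b for b in RNA_ALPHABET if b != arm[p]]
            arm[p] = alternatives[rng.integers(len(alternatives))]
    return m + loop + "".join(arm)


def _instantiate_pattern(pattern: str, rng: np.random.Generator) -> str:
    """One concrete ACGU instance of an IUPAC pattern."""
    out = []
    for ch in pattern:
        bases = IUPAC[ch]
        out.append(bases if len(bases) == 1 else bases[rng.integers(len(bases))])
    return "".join(out)


def _mutate_exact(seq: str, n_mismatch: int, rng: np.random.Generator) -> str:
    """Substitute exactly n_mismatch positions."""
    s = list(seq)
    if n_mismatch:
        for p in rng.choice(len(s), size=n_mismatch, replace=False):
            alternatives = [b for b in RNA_ALPHABET if b != s[p]]
            s[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(s)


def _build_utr(
    cfg: SynthConfig,
    rng: np.random.Generator,
    utr_len: int,
    site_mirnas: list[MiRNARecord],
    element_defs: list,
) -> tuple[str, list[tuple[str, int, int]], list[tuple[str, int, int]]]:
    """Assemble one UTR with planted blocks; returns (seq, site coords, element coords).

    Coordinates are 1-based within the UTR.  The assembly is re-drawn until an
    exhaustive re-scan confirms every planted feature is recoverable exactly at
    its recorded coordinates (no accidental earlier/duplicate matches).
    """
    from . import utr3scan  # local import to avoid a cycle at module load

    comp = None if cfg.background_composition is None else list(cfg.background_composition)
    for _ in range(200):
        # blocks are redrawn on every attempt: a mutated tail block can itself
        # recreate the seed 7-mer, which only a fresh draw can repair
        blocks: list[tuple[str, object]] = []  # (kind tag, payload)
        for mir in site_mirnas:
            tail = mir.tail
            n_mm = len(tail) - round(len(tail) * cfg.tail_complementarity)
            tail_block = _mutate_exact(revcomp(tail), n_mm, rng) if tail else ""
            seq = tail_block + revcomp(mir.seed)
            blocks.append(("site", (mir, seq, len(tail_block))))
        for mdef in element_defs:
            inst = _instantiate_pattern(mdef.pattern, rng)
            if mdef.requires_hairpin:
                stem = _random_seq(rng, max(mdef.min_stem, 5) + 1)
                seq = stem + inst + revcomp(stem)
                loop_off = len(stem)
            else:
                seq, loop_off = inst, 0
            blocks.append(("element", (mdef, seq, loop_off, len(inst))))

        total = sum(len(b[1][1]) for b in blocks)
        if total > utr_len:
            raise ConfigurationError(
                f"planted blocks ({total} nt) do not fit in a {utr_len} nt UTR; widen utr_len_range"
            )

        order = list(rng.permutation(len(blocks))) if blocks else []
        gaps = rng.multinomial(utr_len - total, [1.0 / (len(blocks) + 1)] * (len(blocks) + 1))
        parts, sites, elements = [], [], []
        pos = 0
        for gi, bi in enumerate(order):
            gap = _random_seq(rng, int(gaps[gi]), comp)
            parts.append(gap)
            pos += len(gap)
            kind, payload = blocks[bi]
            seq = payload[1]
            if kind == "site":
                mir, _, off = payload
                sites.append((mir.id, pos + off + 1, pos + off + 7))
            else:
                mdef, _, loop_off, inst_len = payload
                elements.append((mdef.name, pos + loop_off + 1, pos + loop_off + inst_len))
            parts.append(seq)
            pos += len(seq)
        parts.append(_random_seq(rng, int(gaps[len(blocks)]), comp))
        utr = "".join(parts)

        ok = True
        for mid, s, e in sites:
            site7 = utr[s - 1 : e]
            occurrences = [k + 1 for k in range(len(utr) - 6) if utr[k : k + 7] == site7]
            planted_here = [ps for pm, ps, _ in sites if utr[ps - 1 : ps + 6] == site7]
            if occurrences != sorted(planted_here):
                ok = False
                break
        if ok and elements:
            used = [d for d in element_defs]
            hits = utr3scan.scan_utr(utr, used)
            found = {(h.element, h.start, h.end) for h in hits}
            ok = all((name, s, e) in found for name, s, e in elements)
        if ok:
            return utr, sites, elements
    raise ConfigurationError("could not assemble a consistent UTR after 200 attempts")


def gen_transcriptome(
    config: SynthConfig,
) -> tuple[list[TranscriptRecord], list[MiRNARecord], TruthTable]:
    """Generate transcripts, miRNAs and the truth table for one configuration.

    Deterministic given ``config.rng_seed``.  Returned transcripts comprise
    protein-coding mRNAs (with 3'UTR annotation), miRNA precursor transcripts
    and pseudogenes (with ``parent_id`` set).
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    truth = TruthTable()

    # -- miRNAs: unique seeds so seed families are unambiguous ground truth
    mirnas: list[MiRNARecord] = []
    seen_seeds: set[str] = set()
    for i in range(cfg.n_mirna):
        for _ in range(1000):
            mature = _random_seq(rng, cfg.mature_len)
            if seed_of(mature) not in seen_seeds:
                break
        else:  # pragma: no cover - 16384 possible seeds
            raise ConfigurationError("could not draw a unique seed")
        seen_seeds.add(seed_of(mature))
        precursor = make_hairpin(mature, cfg.precursor_loop_len, rng)
        mirnas.append(MiRNARecord(id=f"MIR{i + 1:04d}", mature=mature, precursor=precursor))

    element_defs = []
    if cfg.planted_elements:
        from . import utr3scan

        table = {d.name: d for d in utr3scan.default_motif_table()}
        for name in cfg.planted_elements:
            if name not in table:
                raise ConfigurationError(f"unknown cis-element {name!r}")
            element_defs.append(table[name])

    # round-robin planting over a shuffled miRNA order so coverage is balanced
    plant_order = list(rng.permutation(cfg.n_mirna)) if cfg.n_mirna else []
    plant_cursor = 0

    transcripts: list[TranscriptRecord] = []
    for i in range(cfg.n_mrna):
        cds_len = int(rng.integers(cfg.cds_len_range[0], cfg.cds_len_range[1] + 1))
        utr_len = int(rng.integers(cfg.utr_len_range[0], cfg.utr_len_range[1] + 1))
        if isinstance(cfg.planted_sites_per_utr, int):
            k = cfg.planted_sites_per_utr
        else:
            lo, hi = cfg.planted_sites_per_utr
            k = int(rng.integers(lo, hi + 1))
        site_mirnas = []
        for _ in range(min(k, cfg.n_mirna) if cfg.n_mirna else 0):
            site_mirnas.append(mirnas[plant_order[plant_cursor % cfg.n_mirna]])
            plant_cursor += 1

        cds = _random_seq(
            rng, cds_len, None if cfg.background_composition is None else list(cfg.background_composition)
        )
        utr, sites, elements = _build_utr(cfg, rng, utr_len, site_mirnas, element_defs)
        tid = f"GENE{i + 1:04d}"
        rec = TranscriptRecord(
            id=tid,
            biotype="protein_coding",
            sequence=cds + utr,
            utr3=(cds_len + 1, cds_len + utr_len),
        )
        transcripts.append(rec)
        for mid, s, e in sites:
            truth.planted_interactions.append((mid, tid, cds_len + s, cds_len + e))
        for name, s, e in elements:
            truth.planted_elements.append((tid, name, cds_len + s, cds_len + e))

    for mir in mirnas:
        transcripts.append(TranscriptRecord(id=mir.id, biotype="miRNA", sequence=mir.precursor))

    mrna_records = [t for t in transcripts if t.biotype == "protein_coding"]
    for i in range(cfg.n_pseudogene):
        parent = mrna_records[int(rng.integers(len(mrna_records)))]
        target_identity = float(rng.uniform(*cfg.identity_range))
        pseq = mutate_copy(parent.sequence, target_identity, rng)
        realized = sum(a == b for a, b in zip(pseq, parent.sequence)) / len(pseq)
        pid = f"PSG{i + 1:04d}"
        transcripts.append(
            TranscriptRecord(id=pid, biotype="pseudogene", sequence=pseq, parent_id=parent.id)
        )
        truth.pseudogene_parents.append((pid, parent.id, realized))

    return transcripts, mirnas, truth


def annotation_frame(transcripts: list[TranscriptRecord]) -> pd.DataFrame:
    """Annotation TSV rows: id, biotype, utr3 bounds, parent id."""
    rows = []
    for t in transcripts:
        s, e = t.utr3 if t.utr3 else ("", "")
        rows.append(
            {
                "id": t.id,
                "biotype": t.biotype,
                "utr3_start": s,
                "utr3_end": e,
                "parent_id": t.parent_id or "",
            }
        )
    return pd.DataFrame(rows, columns=["id", "biotype", "utr3_start", "utr3_end", "parent_id"])


def write_bundle(
    transcripts: list[TranscriptRecord],
    mirnas: list[MiRNARecord],
    truth: TruthTable,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write FASTA/TSV files for a generated bundle; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "transcripts": out / "transcripts.fasta",
        "matures": out / "matures.fasta",
        "precursors": out / "precursors.fasta",
        "annotation": out / "annotation.tsv",
        "truth_interactions": out / "truth_interactions.tsv",
        "truth_elements": out / "truth_elements.tsv",
        "truth_pseudogenes": out / "truth_pseudogenes.tsv",
    }
    write_fasta(((t.id, t.sequence) for t in transcripts), paths["transcripts"])
    write_fasta(((m.id, m.mature) for m in mirnas), paths["matures"])
    write_fasta(((m.id, m.precursor) for m in mirnas), paths["precursors"])
    annotation_frame(transcripts).to_csv(paths["annotation"], sep="\t", index=False)
    truth.interactions_frame().to_csv(paths["truth_interactions"], sep="\t", index=False)
    truth.elements_frame().to_csv(paths["truth_elements"], sep="\t", index=False)
    truth.pseudogenes_frame().to_csv(paths["truth_pseudogenes"], sep="\t", index=False)
    return paths
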