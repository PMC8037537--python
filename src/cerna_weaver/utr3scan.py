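"""Scan 3'UTR sequences for cis-regulatory element classes.

Seven element classes are scanned by default (MBE, GAIT, CPE, ARE, MOS-PRE,
GU-rich, UNR) using the IUPAC patterns in the editable packaged table.  For
stem-loop elements (GAIT) a hit additionally requires a flanking stem: a run of
at least ``min_stem`` complementary base pairs between the 30-nt windows
immediately upstream and downstream of the loop match (a heuristic stand-in for
full secondary-structure prediction).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .sequences import PAIRABLE, iupac_regex, require_rna

#: nt examined on each side of a loop match for the stem check.
STEM_WINDOW = 30


@dataclass(frozen=True)
class MotifDef:
    name: str
    pattern: str
    requires_hairpin: bool = False
    min_stem: int = 0
    note: str = ""

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValidationError(f"{self.name}: empty pattern")
        if self.requires_hairpin and self.min_stem < 3:
            raise ValidationError(f"{self.name}: hairpin motifs need min_stem >= 3")


@dataclass(frozen=True)
class MotifHit:
    transcript_id: str
    element: str
    start: int  # 1-based closed interval on the scanned sequence
    end: int
    match: str


def default_motif_table() -> list[MotifDef]:
    """The seven packaged element classes with their default patterns."""
    path = resources.files("cerna_weaver") / "data" / "utr_motifs.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#", dtype=str, keep_default_na=False)
    defs = []
    for row in df.itertuples(index=False):
        defs.append(
            MotifDef(
                name=row.name,
                pattern=row.pattern,
                requires_hairpin=row.requires_hairpin.lower() == "true",
                min_stem=int(row.min_stem),
                note=row.note,
            )
        )
    return defs


def _max_complementary_run(up: str, down: str, min_stem: int) -> bool:
    """True if a stem of >= min_stem contiguous pairs closes the loop.

    ``up`` is the window 5' of the loop, ``down`` the window 3' of it.  The
    stem pairs up[-1-i] with down[j+i] antiparallel; small offsets (<= 3 nt)
    from the loop boundary are tolerated on either side.
    """
    for off_u in range(4):
        for off_d in range(4):
            run = 0
            i = len(up) - 1 - off_u
            j = off_d
            while i >= 0 and j < len(down):
                if up[i] + down[j] in PAIRABLE:
                    run += 1
                    if run >= min_stem:
                        return True
                else:
                    break
                i -= 1
                j += 1
    return False


def scan_utr(
    seq: str,
    table: Sequence[MotifDef] | None = None,
    *,
    transcript_id: str = "",
) -> list[MotifHit]:
    """All non-overlapping leftmost matches of each element in ``seq``.

    Hits are 1-based closed intervals; for hairpin-gated motifs only matches
    with a satisfying flanking stem are reported.  Hits are sorted by
    (start, element name).
    """
    s = require_rna(seq, what="UTR sequence")
    if table is None:
        table = default_motif_table()
    hits: list[MotifHit] = []
    for mdef in table:
        rx = iupac_regex(mdef.pattern)
        for m in rx.finditer(s):
            start, end = m.start() + 1, m.end()
            if mdef.requires_hairpin:
                up = s[max(0, m.start() - STEM_WINDOW) : m.start()]
                down = s[m.end() : m.end() + STEM_WINDOW]
                if not _max_complementary_run(up, down, mdef.min_stem):
                    continue
            hits.append(MotifHit(transcript_id, mdef.name, start, end, m.group(0)))
    return sorted(hits, key=lambda h: (h.start, h.element))


def element_profile(
    hits_by_transcript: dict[str, list[MotifHit]],
    gene_panel: Iterable[str],
    table: Sequence[MotifDef] | None = None,
) -> pd.DataFrame:
    """Genes x elements presence/absence matrix (booleans)."""
    if table is None:
        table = default_motif_table()
    names = [d.name for d in table]
    rows = {}
    for gene in gene_panel:
        present = {h.element for h in hits_by_transcript.get(gene, [])}
        rows[gene] = [e in present for e in names]
    return pd.DataFrame.from_dict(rows, orient="index", columns=names)


def hits_frame(hits: Iterable[MotifHit]) -> pd.DataFrame:
    """BED-like TSV rows for a hit list."""
    return pd.DataFrame(
        [(h.transcript_id, h.start, h.end, h.element, h.match) for h in hits],
        columns=["transcript_id", "start", "end", "element", "match"],
    )
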