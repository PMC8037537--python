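"""Transcript biotype census, pseudogene/parent identity, and packaged table fixtures.

The census tallies transcripts into the eight Ensembl-style biotypes the
annotation distinguishes (protein_coding plus seven noncoding classes) and
summarizes the coding/noncoding breakdown.  Pseudogene-to-parent similarity is
computed as global-alignment percent identity over all alignment columns,
including gap columns (the "identities / alignment length" convention).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd
from Bio import Align

from .errors import ValidationError
from .records import BIOTYPES
from .sequences import require_rna

#: Names of the packaged reference-table fixtures.
FIXTURE_NAMES = (
    "conserved_mirnas",
    "specific_mirnas",
    "pseudogenes",
    "pathway_interactions",
    "biotype_counts",
)


@dataclass
class BiotypeCensus:
    """Per-biotype tallies plus the coding/noncoding summary."""

    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def noncoding_total(self) -> int:
        return self.total - self.counts.get("protein_coding", 0)

    @property
    def fraction_noncoding(self) -> float:
        return self.noncoding_total / self.total if self.total else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [(b, self.counts.get(b, 0)) for b in sorted(BIOTYPES)]
        return pd.DataFrame(rows, columns=["biotype", "count"])


def classify_biotypes(annotation: Iterable[Mapping[str, object]] | pd.DataFrame) -> BiotypeCensus:
    """Tally transcripts by biotype.

    ``annotation`` is an iterable of mappings (or a DataFrame) with at least a
    ``biotype`` column; a ``count`` column, when present, weights the row (so a
    pre-aggregated table can be tallied too).  Unrecognized biotype labels are
    rejected with the offending row named.
    """
    if isinstance(annotation, pd.DataFrame):
        annotation = annotation.to_dict("records")
    counts: Counter[str] = Counter()
    for i, row in enumerate(annotation):
        biotype = row.get("biotype")
        if biotype not in BIOTYPES:
            ident = row.get("id", f"row {i}")
            raise ValidationError(f"{ident}: unrecognized biotype {biotype!r}")
        counts[str(biotype)] += int(row.get("count", 1))
    return BiotypeCensus(dict(counts))


def _global_aligner(match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def percent_identity(
    a: str,
    b: str,
    *,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> tuple[float, int]:
    """Global-alignment identity between two sequences.

    Returns ``(identity, alignment_length)`` where identity = matching columns /
    total alignment columns (gap columns included) of an optimal
    Needleman-Wunsch alignment under unit-style scores (match +1, mismatch -1,
    gap -2 by default).
    """
    a = require_rna(a, what="first sequence")
    b = require_rna(b, what="second sequence")
    aligner = _global_aligner(match, mismatch, gap)
    aln = aligner.align(a, b)[0]
    columns = aln.shape[1]
    matches = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        sa, sb = a[a0:a1], b[b0:b1]
        matches += sum(x == y for x, y in zip(sa, sb))
    return matches / columns, int(columns)


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged reference tables, verbatim, in stable row order."""
    if name not in FIXTURE_NAMES:
        raise ValidationError(f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}")
    path = resources.files("cerna_weaver") / "data" / "fixtures" / f"{name}.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment=None, dtype=str, keep_default_na=False)
    if "count" in df.columns:
        df["count"] = df["count"].astype(int)
    if "identity_pct" in df.columns:
        df["identity_pct"] = df["identity_pct"].astype(float)
    return df
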