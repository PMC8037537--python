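"""Core domain records shared by the analysis stages.

A :class:`TranscriptRecord` is one transcript with its biotype and optional
3'UTR annotation; a :class:`MiRNARecord` bundles a precursor, its mature
sequence and the derived seed (mature positions 2-8, 1-based closed); a
:class:`DuplexInteraction` is one predicted miRNA:target pairing that survived
the dissimilarity and free-energy filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import ValidationError
from .sequences import require_rna

#: Recognized transcript biotypes (Ensembl-style labels).
BIOTYPES = frozenset(
    {"protein_coding", "miRNA", "pseudogene", "snRNA", "snoRNA", "rRNA", "miscRNA", "mtRNA"}
)

NONCODING_BIOTYPES = BIOTYPES - {"protein_coding"}


@dataclass
class TranscriptRecord:
    """One transcript: id, biotype, sequence, optional 3'UTR bounds and parent.

    ``utr3`` is a 1-based closed interval on ``sequence``; ``parent_id`` is
    only meaningful for pseudogenes (the parental gene the copy degenerated
    from).
    """

    id: str
    biotype: str
    sequence: str
    utr3: Optional[tuple[int, int]] = None
    parent_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValidationError(f"{self.id}: unrecognized biotype {self.biotype!r}")
        self.sequence = require_rna(self.sequence, what=f"sequence of {self.id}")
        if self.utr3 is not None:
            s, e = self.utr3
            if not (1 <= s <= e <= len(self.sequence)):
                raise ValidationError(f"{self.id}: utr3 {self.utr3} outside sequence bounds")
        if self.parent_id is not None and self.biotype != "pseudogene":
            raise ValidationError(f"{self.id}: parent_id set on non-pseudogene biotype")

    @property
    def utr3_seq(self) -> str:
        """The annotated 3'UTR slice, or '' when not annotated."""
        if self.utr3 is None:
            return ""
        s, e = self.utr3
        return self.sequence[s - 1 : e]

    @property
    def searchable_region(self) -> tuple[int, int]:
        """Region scanned for miRNA sites: the 3'UTR for mRNAs, everything else full-length."""
        if self.biotype == "protein_coding" and self.utr3 is not None:
            return self.utr3
        return (1, len(self.sequence))


def seed_of(mature: str) -> str:
    """Seed = mature positions 2-8 (1-based closed), 7 nt."""
    m = require_rna(mature, what="mature miRNA")
    if len(m) < 8:
        raise ValidationError(f"mature miRNA too short for a seed ({len(m)} nt < 8)")
    return m[1:8]


@dataclass
class MiRNARecord:
    """A miRNA: precursor hairpin, mature sequence, derived 7-nt seed."""

    id: str
    mature: str
    precursor: str = ""
    conserved: bool = False
    seed: str = field(init=False)

    def __post_init__(self) -> None:
        self.mature = require_rna(self.mature, what=f"mature of {self.id}")
        if self.precursor:
            self.precursor = require_rna(self.precursor, what=f"precursor of {self.id}")
            if self.mature not in self.precursor:
                raise ValidationError(f"{self.id}: mature is not a substring of precursor")
        self.seed = seed_of(self.mature)

    @property
    def tail(self) -> str:
        """Everything 3' of the seed (mature positions 9..end); may be empty."""
        return self.mature[8:]


@dataclass
class DuplexInteraction:
    """One retained miRNA<->target pairing with site, dissimilarity and deltaG (kcal/mol)."""

    mirna_id: str
    target_id: str
    target_kind: str  # "mRNA" or "pseudogene"
    site_start: int
    site_end: int
    dissimilarity: float
    delta_g: float

    def __post_init__(self) -> None:
        if self.target_kind not in {"mRNA", "pseudogene"}:
            raise ValidationError(f"bad target_kind {self.target_kind!r}")
        if not (1 <= self.site_start <= self.site_end):
            raise ValidationError("bad site interval")


@dataclass
class AlignmentHit:
    """Best local alignment of a query against a subject."""

    query_id: str
    subject_id: str
    score: int
    evalue: float
    query_interval: tuple[int, int]  # 1-based closed; (0, 0) for an empty hit
    subject_interval: tuple[int, int]

    @property
    def empty(self) -> bool:
        return self.score <= 0
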