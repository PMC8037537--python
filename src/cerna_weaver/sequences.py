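"""RNA sequence helpers.

All sequences are handled internally in the RNA alphabet (ACGU, uppercase).
FASTA input written in the DNA convention (T) is transparently mapped to U on
read; lowercase is uppercased.  Coordinates everywhere in the package are
1-based, fully closed intervals.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError

RNA_ALPHABET = "ACGU"

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: IUPAC nucleotide codes (RNA convention) -> the set of concrete bases.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}

#: Base pairs allowed in a duplex: Watson-Crick plus GU wobble.
PAIRABLE = {"AU", "UA", "CG", "GC", "GU", "UG"}


def to_rna(seq: str) -> str:
    """Uppercase and map T->U."""
    return seq.upper().replace("T", "U")


def require_rna(seq: str, *, what: str = "sequence") -> str:
    """Uppercase/map a sequence and reject anything outside ACGU."""
    s = to_rna(seq)
    if not s:
        raise ValidationError(f"empty {what}")
    bad = set(s) - set(RNA_ALPHABET)
    if bad:
        raise ValidationError(f"{what} contains non-ACGU symbols: {sorted(bad)}")
    return s


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC pattern (U/T-equivalent on input) into a regex."""
    parts = []
    for ch in to_rna(pattern):
        try:
            bases = IUPAC[ch]
        except KeyError:
            raise ValidationError(f"unknown IUPAC code {ch!r} in pattern {pattern!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, RNA sequence) pairs; DNA input is mapped to RNA."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, to_rna(str(rec.seq))


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as wrapped FASTA (deterministic layout)."""
    seqrecs = (SeqRecord(Seq(seq), id=name, description="") for name, seq in records)
    SeqIO.write(seqrecs, str(path), "fasta")
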