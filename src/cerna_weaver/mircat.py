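"""miRNA cataloguing: seed extraction, seed families, local alignment and E-values.

Unknown precursors are annotated by aligning them against a catalogue of
mature miRNAs with a Smith-Waterman local aligner and gating the best hit on a
Karlin-Altschul E-value (E = K * m * n * exp(-lambda * S)).  Two gates are
reported: the primary acceptance gate (E below ``e_cut``, default 1e-5, the
conventional "good Blast hit" threshold) and a secondary, score-based gate
(E < 0.05 and S > 100) carried as a labelled column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError, ValidationError
from .records import AlignmentHit, MiRNARecord, seed_of
from .sequences import require_rna

extract_seed = seed_of  # public alias: the seed is mature positions 2-8


@dataclass(frozen=True)
class Scoring:
    """Local-alignment scores (defaults: nucleotide Blast-like +2/-3, linear gap -5)."""

    match: int = 2
    mismatch: int = -3
    gap: int = -5


#: Ungapped nucleotide Karlin-Altschul parameters for the default scoring.
DEFAULT_LAMBDA = 0.625
DEFAULT_K = 0.41


def seed_families(catalog: Iterable[MiRNARecord]) -> dict[str, list[str]]:
    """Partition a catalogue by exact seed; values are sorted member id lists."""
    groups: dict[str, list[str]] = {}
    for rec in catalog:
        groups.setdefault(rec.seed, []).append(rec.id)
    return {seed: sorted(ids) for seed, ids in groups.items()}


def _sw_matrix(q: str, s: str, scoring: Scoring) -> list[list[int]]:
    n, m = len(q), len(s)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        qi = q[i - 1]
        row = H[i]
        prev = H[i - 1]
        for j in range(1, m + 1):
            sub = scoring.match if qi == s[j - 1] else scoring.mismatch
            row[j] = max(0, prev[j - 1] + sub, prev[j] + scoring.gap, row[j - 1] + scoring.gap)
    return H


def align_local(
    query: str,
    subject: str,
    scoring: Scoring = Scoring(),
    *,
    query_id: str = "query",
    subject_id: str = "subject",
    lam: float = DEFAULT_LAMBDA,
    K: float = DEFAULT_K,
) -> AlignmentHit:
    """Smith-Waterman optimum with a deterministic tie-break.

    Among co-optimal local alignments the one with the lowest subject start,
    then lowest query start, is reported (traceback prefers diagonal moves).
    A best score of 0 yields an empty hit with intervals (0, 0).
    """
    q = require_rna(query, what="query")
    s = require_rna(subject, what="subject")
    H = _sw_matrix(q, s, scoring)
    best = max(max(row) for row in H)
    if best <= 0:
        e = evalue(0, len(q), len(s), lam, K)
        return AlignmentHit(query_id, subject_id, 0, e, (0, 0), (0, 0))

    candidates = []
    for i in range(1, len(q) + 1):
        for j in range(1, len(s) + 1):
            if H[i][j] == best:
                # greedy deterministic traceback: diagonal > up > left
                ci, cj = i, j
                while H[ci][cj] > 0:
                    sub = scoring.match if q[ci - 1] == s[cj - 1] else scoring.mismatch
                    if ci and cj and H[ci][cj] == H[ci - 1][cj - 1] + sub:
                        ci, cj = ci - 1, cj - 1
                    elif ci and H[ci][cj] == H[ci - 1][cj] + scoring.gap:
                        ci -= 1
                    else:
                        cj -= 1
                candidates.append((cj + 1, ci + 1, j, i))  # subject start, query start, ends
    sub_start, q_start, sub_end, q_end = min(candidates)
    e = evalue(best, len(q), len(s), lam, K)
    return AlignmentHit(query_id, subject_id, best, e, (q_start, q_end), (sub_start, sub_end))


def evalue(S: float, m: int, n: int, lam: float = DEFAULT_LAMBDA, K: float = DEFAULT_K) -> float:
    """Karlin-Altschul expected number of chance alignments scoring >= S."""
    if S < 0:
        raise ValidationError("alignment score must be >= 0")
    if m < 1 or n < 1:
        raise ValidationError("sequence lengths must be >= 1")
    if lam <= 0 or K <= 0:
        raise ConfigurationError("lambda and K must be positive")
    return K * m * n * math.exp(-lam * S)


def annotate_precursors(
    unknowns: Sequence[tuple[str, str]],
    catalog: Sequence[tuple[str, str]],
    e_cut: float = 1e-5,
    scoring: Scoring = Scoring(),
    lam: float = DEFAULT_LAMBDA,
    K: float = DEFAULT_K,
) -> pd.DataFrame:
    """Annotate unknown precursors against a mature-miRNA catalogue.

    ``unknowns`` and ``catalog`` are (id, sequence) pairs.  For each unknown
    the best-scoring catalogue mature is found (ties broken by higher score,
    then lexicographic subject id); its E-value uses the total catalogue
    length as the search-space size.  Columns: query_id, subject_id, score,
    evalue, accepted (E < e_cut) and accepted_score_gate (E < 0.05 and S > 100).
    """
    if not catalog:
        raise ValidationError("catalogue must be non-empty")
    n_total = sum(len(require_rna(seq)) for _, seq in catalog)
    rows = []
    for uid, useq in unknowns:
        best_hit: AlignmentHit | None = None
        for sid, sseq in sorted(catalog):
            hit = align_local(useq, sseq, scoring, query_id=uid, subject_id=sid, lam=lam, K=K)
            if best_hit is None or hit.score > best_hit.score:
                best_hit = hit
        assert best_hit is not None
        e = evalue(best_hit.score, len(useq), n_total, lam, K)
        rows.append(
            {
                "query_id": uid,
                "subject_id": best_hit.subject_id if not best_hit.empty else "",
                "score": best_hit.score,
                "evalue": e,
                "accepted": bool(e < e_cut and not best_hit.empty),
                "accepted_score_gate": bool(e < 0.05 and best_hit.score > 100),
            }
        )
    return pd.DataFrame(rows, columns=["query_id", "subject_id", "score", "evalue", "accepted", "accepted_score_gate"])
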