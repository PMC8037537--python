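"""Term/pathway enrichment: Fisher's exact test, the EASE variant, and BH-FDR.

For a study set of K genes drawn from a population of N, a term annotating n
population genes and hitting k study genes is scored by the one-sided
hypergeometric upper tail P(X >= k) (Fisher), its conservative EASE variant
(the same tail with one study hit removed, P(X >= k-1), defined as 1 when
k <= 1), and a Benjamini-Hochberg step-up q-value across all emitted terms.
Default gates mirror common annotation-tool practice: p < 0.05, q < 0.05,
EASE <= 0.1.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

ROW_COLUMNS = [
    "term_id",
    "term_name",
    "k",
    "K",
    "n",
    "N",
    "p_fisher",
    "p_ease",
    "q_benjamini",
]


def fisher_p(k: int, K: int, n: int, N: int) -> float:
    """One-sided hypergeometric upper tail P(X >= k)."""
    _check_counts(k, K, n, N)
    return float(stats.hypergeom.sf(k - 1, N, n, K))


def ease_p(k: int, K: int, n: int, N: int) -> float:
    """EASE score: the Fisher tail recomputed with one study hit removed."""
    _check_counts(k, K, n, N)
    if k <= 1:
        return 1.0
    return float(stats.hypergeom.sf(k - 2, N, n, K))


def _check_counts(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= k <= min(K, n) and 0 < K <= N and 0 <= n <= N):
        raise ValidationError(f"invalid contingency counts k={k} K={K} n={n} N={N}")


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """Step-up BH q-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrich(
    study: Iterable[str],
    population: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    term_names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Enrichment rows (one per term with >= 1 study hit), sorted by p_fisher.

    ``term_map`` maps term id -> annotated genes; genes outside the population
    are ignored.  The study must be a subset of the population.
    """
    pop = set(population)
    stu = set(study)
    if not stu <= pop:
        missing = sorted(stu - pop)[:5]
        raise ValidationError(f"study genes absent from population: {missing}")
    N, K = len(pop), len(stu)
    rows = []
    for term_id in sorted(term_map):
        genes = set(term_map[term_id]) & pop
        k = len(genes & stu)
        if k == 0:
            continue
        n = len(genes)
        rows.append(
            {
                "term_id": term_id,
                "term_name": (term_names or {}).get(term_id, term_id),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_fisher": fisher_p(k, K, n, N),
                "p_ease": ease_p(k, K, n, N),
            }
        )
    df = pd.DataFrame(rows, columns=ROW_COLUMNS[:-1])
    df["q_benjamini"] = benjamini_hochberg(df["p_fisher"].to_numpy()) if len(df) else []
    return df.sort_values("p_fisher", kind="stable", ignore_index=True)


def filter_significant(
    rows: pd.DataFrame,
    p_cut: float = 0.05,
    q_cut: float = 0.05,
    ease_cut: float = 0.1,
) -> pd.DataFrame:
    """Keep rows with p_fisher < p_cut AND q_benjamini < q_cut AND p_ease <= ease_cut."""
    if rows.empty:
        return rows
    keep = (rows["p_fisher"] < p_cut) & (rows["q_benjamini"] < q_cut) & (rows["p_ease"] <= ease_cut)
    return rows[keep].reset_index(drop=True)


def synthetic_term_map(
    population: Sequence[str],
    n_terms: int = 20,
    size_range: tuple[int, int] = (10, 40),
    rng_seed: int = 0,
) -> dict[str, list[str]]:
    """Random term->genes map over a population, for testing and synthetic runs."""
    rng = np.random.default_rng(rng_seed)
    pop = list(population)
    out = {}
    for i in range(n_terms):
        size = int(rng.integers(size_range[0], min(size_range[1], len(pop)) + 1))
        genes = rng.choice(len(pop), size=size, replace=False)
        out[f"TERM{i + 1:04d}"] = sorted(pop[g] for g in genes)
    return out
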