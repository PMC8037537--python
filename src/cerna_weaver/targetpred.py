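"""SOM-based miRNA target prediction with a duplex free-energy filter.

The predictor works in four stages:

1. a self-organizing map (SOM) is trained on the one-hot encodings of all
   catalogued 7-nt miRNA seeds, clustering seeds by sequence similarity;
2. every seed-length window of a target's searchable region (the 3'UTR for
   mRNAs, the whole sequence for pseudogenes) is reverse-complemented,
   encoded and projected onto the trained map; a window is a candidate site
   for every catalogued seed sharing its best-matching unit (BMU);
3. for each candidate, the dissimilarity between the miRNA tail (mature
   positions 9..end) and the reverse complement of the fragment extension
   (the |tail| + max_bulge nt 5' of the site) is computed by a bulge-aware
   unit-cost alignment; candidates above the threshold tau are dropped;
4. the binding free energy of the mature against the site-plus-extension
   context is computed by a nearest-neighbor dynamic program (Watson-Crick +
   GU stacks, affine bulge penalties, duplex initiation) and interactions
   with deltaG at or above the cut (default -12 kcal/mol) are discarded.

Training is batch-mode (results independent of input order) and fully
deterministic given the RNG seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .records import DuplexInteraction, MiRNARecord, TranscriptRecord
from .sequences import PAIRABLE, RNA_ALPHABET, require_rna, revcomp

_BASE_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}


# ---------------------------------------------------------------------------
# seed encoding

def encode_seed(seq: str) -> np.ndarray:
    """One-hot encode an ACGU string (4 slots per position); invertible."""
    s = require_rna(seq, what="seed")
    vec = np.zeros(4 * len(s))
    for i, ch in enumerate(s):
        vec[4 * i + _BASE_INDEX[ch]] = 1.0
    return vec


def decode_seed(vec: np.ndarray) -> str:
    """Invert :func:`encode_seed` (argmax per position)."""
    v = np.asarray(vec).reshape(-1, 4)
    return "".join(RNA_ALPHABET[int(i)] for i in v.argmax(axis=1))


# ---------------------------------------------------------------------------
# SOM

@dataclass
class SOMLattice:
    """A trained 2-D SOM: grid shape, weights and the seed->BMU assignment."""

    rows: int
    cols: int
    weights: np.ndarray  # (rows*cols, dim)
    epochs: int
    lr0: float
    radius0: float
    rng_seed: int
    bmu_map: dict[str, int] = field(default_factory=dict)  # seed string -> neuron index

    def bmu(self, vec: np.ndarray) -> int:
        """Best-matching unit; ties break to the lowest row-major index."""
        d = np.linalg.norm(self.weights - vec, axis=1)
        return int(d.argmin())

    def bmu_batch(self, X: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - self.weights[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


def default_grid_side(n: int) -> int:
    """Default square-grid side: ceil(sqrt(5 * sqrt(n)))."""
    return max(1, math.ceil(math.sqrt(5.0 * math.sqrt(max(n, 1)))))


def train_som(
    seeds: Sequence[str],
    rows: int | None = None,
    cols: int | None = None,
    epochs: int = 100,
    lr0: float = 0.5,
    radius0: float | None = None,
    rng_seed: int = 0,
) -> SOMLattice:
    """Train a batch SOM on one-hot encoded seed strings.

    Batch updates (BMU assignment of all inputs, then a Gaussian-neighborhood
    weighted mean blended into the weights) make the result independent of the
    input order.  Learning rate and neighborhood radius decay linearly.
    """
    uniq = sorted(set(seeds))
    if not uniq:
        raise ValidationError("at least one seed is required")
    X = np.stack([encode_seed(s) for s in uniq])
    n, dim = X.shape
    if rows is None:
        rows = default_grid_side(n)
    if cols is None:
        cols = rows
    if rows * cols < 1:
        raise ConfigurationError("grid must contain at least one neuron")
    if radius0 is None:
        radius0 = max(rows, cols) / 2.0

    rng = np.random.default_rng(rng_seed)
    W = rng.uniform(0.0, 1.0, size=(rows * cols, dim))
    grid = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=float)
    grid_d2 = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(axis=2)

    lr_min = 0.01
    for t in range(epochs):
        frac = t / max(epochs - 1, 1)
        lr = lr0 + (lr_min - lr0) * frac
        radius = max(radius0 * (1.0 - frac), 0.5)
        d2 = ((X[:, None, :] - W[None, :, :]) ** 2).sum(axis=2)
        bmus = d2.argmin(axis=1)
        h = np.exp(-grid_d2[bmus] / (2.0 * radius * radius))  # (n, K)
        denom = h.sum(axis=0)
        numer = h.T @ X
        active = denom > 1e-12
        target = W.copy()
        target[active] = numer[active] / denom[active, None]
        W = (1.0 - lr) * W + lr * target

    lattice = SOMLattice(rows, cols, W, epochs, lr0, radius0, rng_seed)
    for s, b in zip(uniq, lattice.bmu_batch(X)):
        lattice.bmu_map[s] = int(b)
    return lattice


# ---------------------------------------------------------------------------
# fragment projection

def project_fragments(
    lattice: SOMLattice,
    target: TranscriptRecord,
    seed_to_ids: dict[str, list[str]],
    seed_len: int = 7,
) -> list[tuple[str, str, int, int]]:
    """Candidate (mirna_id, seed, site_start, site_end) tuples for one target.

    Slides a ``seed_len`` window (stride 1) over the target's searchable
    region, reverse-complements and encodes each window, finds its BMU, and
    emits a candidate for every catalogued seed assigned to the same BMU.
    Coordinates are 1-based on the full target sequence.
    """
    lo, hi = target.searchable_region
    region = target.sequence[lo - 1 : hi]
    if len(region) < seed_len:
        return []
    neuron_seeds: dict[int, list[str]] = {}
    for seed, b in lattice.bmu_map.items():
        neuron_seeds.setdefault(b, []).append(seed)

    # vectorized window encoding: (n_windows, 4*seed_len)
    codes = np.array([_BASE_INDEX[c] for c in revcomp(region)])
    n_win = len(region) - seed_len + 1
    idx = np.arange(seed_len)[None, :] + np.arange(n_win)[:, None]
    onehot = np.eye(4)[codes[idx]].reshape(n_win, 4 * seed_len)
    d2 = ((onehot[:, None, :] - lattice.weights[None, :, :]) ** 2).sum(axis=2)
    bmus = d2.argmin(axis=1)

    out: list[tuple[str, str, int, int]] = []
    # window w (0-based on region, forward strand) corresponds to reverse-strand
    # window n_win-1-w in the revcomp ordering
    for w in range(n_win):
        b = int(bmus[n_win - 1 - w])
        for seed in neuron_seeds.get(b, ()):  # seeds hosted by this BMU
            start = lo + w
            for mid in seed_to_ids.get(seed, ()):
                out.append((mid, seed, start, start + seed_len - 1))
    return out


# ---------------------------------------------------------------------------
# tail dissimilarity

def tail_dissimilarity(mirna_tail: str, extended_fragment: str, max_bulge: int = 4) -> float:
    """Bulge-aware unit-cost dissimilarity between tail and revcomp(extension).

    The tail is aligned globally (anchored at the seed-proximal end) against
    the reverse complement of the extension; matches cost 0, mismatches and
    gaps cost 1, with at most ``max_bulge`` total gaps; trailing extension is
    free.  The cost is divided by the tail length and clipped to [0, 1].
    """
    if not mirna_tail:
        return 0.0
    tail = require_rna(mirna_tail, what="tail")
    rc = revcomp(require_rna(extended_fragment, what="extension")) if extended_fragment else ""
    m, n = len(tail), len(rc)
    if n < m - max_bulge:
        return 1.0  # extension too short to absorb the tail within the gap budget
    INF = float("inf")
    # dp[i][j]: cost aligning tail[:i] vs rc[:j]; band |i-j| <= max_bulge
    dp = [[INF] * (n + 1) for _ in range(m + 1)]
    dp[0][0] = 0.0
    for j in range(1, min(n, max_bulge) + 1):
        dp[0][j] = float(j)
    for i in range(1, m + 1):
        if i - 0 <= max_bulge:
            dp[i][0] = float(i)
        for j in range(max(1, i - max_bulge), min(n, i + max_bulge) + 1):
            sub = 0.0 if tail[i - 1] == rc[j - 1] else 1.0
            best = dp[i - 1][j - 1] + sub
            if abs(i - (j - 1)) <= max_bulge:
                best = min(best, dp[i][j - 1] + 1.0)
            if abs((i - 1) - j) <= max_bulge:
                best = min(best, dp[i - 1][j] + 1.0)
            dp[i][j] = best
    cost = min(dp[m][j] for j in range(max(0, m - max_bulge), n + 1))
    if not math.isfinite(cost):
        cost = float(m)
    return min(cost / m, 1.0)


# ---------------------------------------------------------------------------
# duplex free energy

@dataclass
class EnergyModel:
    """Nearest-neighbor duplex parameters (stack table, bulge penalties, initiation)."""

    stacks: dict[tuple[str, str], float]
    bulge_open: float = 3.0  # kcal/mol per bulge/loop event
    bulge_extend: float = 0.5  # kcal/mol per unpaired nt beyond the first
    initiation: float = 4.09  # kcal/mol duplex initiation

    def stack(self, pair1: str, pair2: str) -> float:
        try:
            return self.stacks[(pair1, pair2)]
        except KeyError:
            # strand-flip symmetry: (p1,p2) == (reverse(p2), reverse(p1))
            return self.stacks[(pair2[::-1], pair1[::-1])]


def load_energy_model() -> EnergyModel:
    """Load the packaged stack-energy table and complete it by symmetry."""
    path = resources.files("cerna_weaver") / "data" / "rna_stack_energies.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#", dtype=str)
    stacks: dict[tuple[str, str], float] = {}
    for row in df.itertuples(index=False):
        v = float(row.dG)
        if v > 0:
            raise ConfigurationError(f"stack energy {row.pair1}/{row.pair2} must be <= 0")
        stacks[(row.pair1, row.pair2)] = v
        stacks.setdefault((row.pair2[::-1], row.pair1[::-1]), v)
    for p1 in PAIRABLE:
        for p2 in PAIRABLE:
            if (p1, p2) not in stacks:
                raise ConfigurationError(f"stack table incomplete: missing {p1}/{p2}")
    return EnergyModel(stacks)


def duplex_energy(mirna: str, site_with_context: str, model: EnergyModel | None = None) -> float:
    """Minimum free energy (kcal/mol) of the antiparallel miRNA:site duplex.

    The best co-linear set of Watson-Crick/GU pairs is found by dynamic
    programming: stacks contribute when pairs are adjacent on both strands,
    interruptions cost ``bulge_open`` plus ``bulge_extend`` per unpaired nt
    beyond the first, and the duplex pays one initiation term.  With no
    possible pair the result is the initiation alone.
    """
    if model is None:
        model = load_energy_model()
    q = require_rna(mirna, what="miRNA")
    t = require_rna(site_with_context, what="site context")[::-1]  # antiparallel partner
    n, m = len(q), len(t)
    INF = float("inf")
    # P[i][j]: best energy of a pairing ending with pair (q[i], t[j])
    # M[i][j]: min over k<=i, l<=j of P[k][l] + 0.5*((i-k) + (j-l))
    P = [[INF] * m for _ in range(n)]
    M = [[INF] * m for _ in range(n)]
    best = INF
    ext = model.bulge_extend
    for i in range(n):
        for j in range(m):
            pair = q[i] + t[j]
            if pair in PAIRABLE:
                e = 0.0  # open a new helix
                if i and j:
                    prev = q[i - 1] + t[j - 1]
                    if prev in PAIRABLE and P[i - 1][j - 1] < INF:
                        e = min(e, P[i - 1][j - 1] + model.stack(prev, pair))
                    if M[i - 1][j - 1] < INF:
                        # close a bulge/internal loop of (i-1-k)+(j-1-l) >= 1 nt
                        e = min(e, M[i - 1][j - 1] + model.bulge_open - ext)
                P[i][j] = e
                best = min(best, e)
            mij = P[i][j]
            if i:
                mij = min(mij, M[i - 1][j] + ext)
            if j:
                mij = min(mij, M[i][j - 1] + ext)
            M[i][j] = mij
    if best is INF or best > 0:
        best = 0.0
    return model.initiation + best


# ---------------------------------------------------------------------------
# full pipeline

@dataclass
class PredictParams:
    """Tunables of the prediction pipeline."""

    tau: float = 0.3  # tail dissimilarity threshold
    dg_cut: float = -12.0  # kcal/mol; keep deltaG < dg_cut
    max_bulge: int = 4
    seed_len: int = 7
    som_rows: int | None = None
    som_cols: int | None = None
    som_epochs: int = 100
    som_lr0: float = 0.5
    som_seed: int = 0


@dataclass
class PredictStats:
    """Per-run funnel counts."""

    candidates: int = 0
    passed_tau: int = 0
    passed_dg: int = 0


def predict(
    mirnas: Sequence[MiRNARecord],
    targets: Sequence[TranscriptRecord],
    params: PredictParams | None = None,
    model: EnergyModel | None = None,
    lattice: SOMLattice | None = None,
) -> tuple[list[DuplexInteraction], PredictStats]:
    """Run the full SOM -> projection -> dissimilarity -> deltaG pipeline.

    Returns retained interactions sorted by deltaG ascending (ties by miRNA
    then target id) plus funnel statistics.  Duplicate (miRNA, target) pairs
    collapse to the single lowest-deltaG site.
    """
    params = params or PredictParams()
    stats = PredictStats()
    if not mirnas or not targets:
        return [], stats
    if model is None:
        model = load_energy_model()
    seed_to_ids: dict[str, list[str]] = {}
    for rec in mirnas:
        seed_to_ids.setdefault(rec.seed, []).append(rec.id)
    for ids in seed_to_ids.values():
        ids.sort()
    by_id = {rec.id: rec for rec in mirnas}
    if lattice is None:
        lattice = train_som(
            list(seed_to_ids),
            rows=params.som_rows,
            cols=params.som_cols,
            epochs=params.som_epochs,
            lr0=params.som_lr0,
            rng_seed=params.som_seed,
        )

    best: dict[tuple[str, str], DuplexInteraction] = {}
    for target in targets:
        kind = "pseudogene" if target.biotype == "pseudogene" else "mRNA"
        region_lo, _ = target.searchable_region
        for mid, seed, s, e in project_fragments(lattice, target, seed_to_ids, params.seed_len):
            stats.candidates += 1
            rec = by_id[mid]
            tail = rec.tail
            ext_lo = max(region_lo, s - len(tail) - params.max_bulge)
            extension = target.sequence[ext_lo - 1 : s - 1]
            d = tail_dissimilarity(tail, extension, params.max_bulge)
            if d > params.tau:
                continue
            stats.passed_tau += 1
            ctx_hi = min(len(target.sequence), e + 1)  # one nt for mature position 1
            context = target.sequence[ext_lo - 1 : ctx_hi]
            dg = duplex_energy(rec.mature, context, model)
            if dg < params.dg_cut:
                stats.passed_dg += 1
                inter = DuplexInteraction(mid, target.id, kind, s, e, round(d, 4), round(dg, 2))
                key = (mid, target.id)
                if key not in best or inter.delta_g < best[key].delta_g:
                    best[key] = inter
    out = sorted(best.values(), key=lambda x: (x.delta_g, x.mirna_id, x.target_id))
    return out, stats


def interactions_frame(interactions: Iterable[DuplexInteraction]) -> pd.DataFrame:
    """TSV rows for predicted interactions."""
    return pd.DataFrame(
        [
            (
                x.mirna_id,
                x.target_id,
                x.target_kind,
                x.site_start,
                x.site_end,
                x.dissimilarity,
                x.delta_g,
            )
            for x in interactions
        ],
        columns=[
            "mirna_id",
            "target_id",
            "target_kind",
            "site_start",
            "site_end",
            "dissimilarity",
            "deltaG_kcal_mol",
        ],
    )
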