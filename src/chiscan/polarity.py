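"""Motif occurrence mapping and replication-strand polarity tests.

Chi motifs are active on the leading strand of replication, so on a
circular chromosome their strand of occurrence switches at the origin
and terminus.  Without knowing ori/ter, polarization still leaves a
footprint: the forward-strand start positions of plus-strand matches
and of minus-strand matches are drawn from different parts of the
replicon, which a two-sample rank-sum test picks up.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from ._codes import encode, encode_word, window_index, word_to_index
from .motifs import reverse_complement

__all__ = [
    "OccurrenceSet",
    "PolarityResult",
    "find_occurrences",
    "find_occurrences_many",
    "polarity_test",
    "same_strand_run_test",
    "exact_rank_sum_p",
]

DEFAULT_ALPHA = 1e-3
DEFAULT_MIN_PER_STRAND = 3
EXACT_MAX_N = 25  # exact rank-sum enumeration up to this per-strand size


@dataclass
class OccurrenceSet:
    """Genomic occurrences of one motif on one replicon.

    A '-' occurrence at position p means the reverse complement of the
    motif occupies forward-strand positions p..p+h-1; positions are
    1-based and sorted ascending.
    """

    motif: str
    replicon_id: str
    occurrences: list[tuple[int, str]]

    def __post_init__(self) -> None:
        self.occurrences = sorted(self.occurrences)

    @property
    def positions(self) -> np.ndarray:
        return np.array([p for p, _ in self.occurrences], dtype=np.int64)

    @property
    def strands(self) -> np.ndarray:
        return np.array([s for _, s in self.occurrences])

    def split_by_strand(self) -> tuple[np.ndarray, np.ndarray]:
        pos = self.positions
        strands = self.strands
        return pos[strands == "+"], pos[strands == "-"]

    def __len__(self) -> int:
        return len(self.occurrences)


@dataclass
class PolarityResult:
    """Outcome of the strand-position rank-sum test."""

    n_plus: int
    n_minus: int
    statistic: float
    p_value: float
    polarized: bool
    indeterminate: bool


def _match_positions(
    indexed: tuple[np.ndarray, np.ndarray],
    junction_indexed: tuple[np.ndarray, np.ndarray] | None,
    L: int,
    h: int,
    target: int,
) -> np.ndarray:
    """1-based forward-strand starts given precomputed window indices."""
    idx, valid = indexed
    hits = np.flatnonzero(valid & (idx == target)) + 1
    if junction_indexed is not None:
        jidx, jvalid = junction_indexed
        jh = np.flatnonzero(jvalid & (jidx == target))
        if jh.size:
            # junction window j starts at genome position L-h+2+j, all
            # of which exceed L-h+1, so no double counting
            hits = np.concatenate([hits, jh + (L - h + 2)])
    return np.sort(hits)


def find_occurrences(genome, motif: str) -> OccurrenceSet:
    """Locate a motif on both strands of a replicon.

    '+' rows are forward-strand matches of the motif; '-' rows are
    forward-strand matches of its reverse complement, recorded at the
    forward-strand start.  Circular replicons are additionally scanned
    across the origin junction without double counting.
    """
    return find_occurrences_many(genome, [motif])[motif]


def find_occurrences_many(
    genome, motifs: list[str]
) -> dict[str, OccurrenceSet]:
    """Batch occurrence scan sharing the window index across motifs."""
    codes = encode(genome.sequence)
    circular = bool(getattr(genome, "circular", False))
    L = codes.size
    out: dict[str, OccurrenceSet] = {}
    by_length: dict[int, tuple] = {}
    for motif in motifs:
        wf = encode_word(motif)
        wr = encode_word(reverse_complement(motif))
        h = wf.size
        if h not in by_length:
            indexed = window_index(codes, h)
            junction_indexed = None
            if circular and L >= h and h >= 2:
                junction = np.concatenate([codes[-(h - 1) :], codes[: h - 1]])
                junction_indexed = window_index(junction, h)
            by_length[h] = (indexed, junction_indexed)
        indexed, junction_indexed = by_length[h]
        occ = [
            (int(p), "+")
            for p in _match_positions(
                indexed, junction_indexed, L, h, word_to_index(wf)
            )
        ]
        occ += [
            (int(p), "-")
            for p in _match_positions(
                indexed, junction_indexed, L, h, word_to_index(wr)
            )
        ]
        out[motif] = OccurrenceSet(
            motif=motif,
            replicon_id=getattr(genome, "replicon_id", ""),
            occurrences=occ,
        )
    return out


def exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration (no ties).

    Independent of scipy: enumerates all C(n+m, n) placements of the x
    ranks among the pooled ranks and doubles the smaller tail of the
    U distribution (clipped at 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size != pooled.size:
        raise ValueError("exact enumeration oracle requires untied values")
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2)
    total = comb(n + m, n)
    all_ranks = list(range(1, n + m + 1))
    le = 0
    ge = 0
    for combo in combinations(all_ranks, n):
        u = sum(combo) - n * (n + 1) / 2
        if u <= u_obs:
            le += 1
        if u >= u_obs:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def polarity_test(
    occ: OccurrenceSet,
    alpha: float = DEFAULT_ALPHA,
    min_per_strand: int = DEFAULT_MIN_PER_STRAND,
) -> PolarityResult:
    """Two-sample Wilcoxon rank-sum of '+' vs '-' start positions.

    Exact enumeration when the smaller strand has <= 25 untied
    occurrences, otherwise normal approximation with tie and continuity
    corrections.  Fewer than `min_per_strand` occurrences on either
    strand makes the test indeterminate, which never counts as
    polarized.
    """
    pos_plus, pos_minus = occ.split_by_strand()
    n_plus, n_minus = pos_plus.size, pos_minus.size
    if min(n_plus, n_minus) < min_per_strand:
        return PolarityResult(
            n_plus, n_minus, float("nan"), float("nan"), False, True
        )
    pooled = np.concatenate([pos_plus, pos_minus])
    has_ties = np.unique(pooled).size != pooled.size
    use_exact = min(n_plus, n_minus) <= EXACT_MAX_N and not has_ties
    res = stats.mannwhitneyu(
        pos_plus,
        pos_minus,
        alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
        use_continuity=True,
    )
    p = float(res.pvalue)
    return PolarityResult(
        n_plus=n_plus,
        n_minus=n_minus,
        statistic=float(res.statistic),
        p_value=p,
        polarized=bool(p < alpha),
        indeterminate=False,
    )


def same_strand_run_test(
    occ: OccurrenceSet, n_permutations: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Fraction of position-adjacent pairs on the same strand, with a
    strand-label permutation p-value (one-sided, upper)."""
    if len(occ) < 2:
        raise ValueError("need at least 2 occurrences")
    strands = occ.strands  # already position-sorted
    labels = (strands == "+").astype(np.int8)

    def _stat(lab: np.ndarray) -> float:
        return float(np.mean(lab[1:] == lab[:-1]))

    observed = _stat(labels)
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_permutations):
        if _stat(rng.permutation(labels)) >= observed:
            ge += 1
    p = (1 + ge) / (1 + n_permutations)
    return observed, float(p)
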