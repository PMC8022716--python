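"""Word counts and overrepresentation z-scores under Markov null models.

A word w of length h is scored against a Markov model of order m
(0 <= m <= h-2) fitted on the very sequences being scored (plug-in).
The expected count is the classical estimator

    E_m(w) = prod_{j=1..h-m} N(w_j..w_{j+m}) / prod_{j=2..h-m} N(w_j..w_{j+m-1})

with N(.) the observed k-mer counts and N(empty) the total number of
1-mer windows.  The standard deviation of the count comes from a
parametric bootstrap by default: B sequence sets are simulated from the
fitted chain with the same per-sequence lengths, and the sample sd of
the word count across replicates is used, yielding the Gaussian
z = (observed - expected) / sd.  An analytic asymptotic variance with
self-overlap corrections is available as a fast path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import _codes
from ._codes import (
    concat_with_breaks,
    count_word_codes,
    encode,
    encode_word,
    index_to_word,
    kmer_count_array,
    sim_count_all,
    sim_count_word,
    simulate_concat,
    word_to_index,
)

__all__ = [
    "MarkovModel",
    "WordStatistic",
    "count_word",
    "count_all_kmers",
    "fit_markov",
    "expected_count",
    "simulate_from_model",
    "null_distribution",
    "zscore_word",
    "score_all_models",
]

DEFAULT_ORDERS = (0, 1, 2, 3, 4, 5)
DEFAULT_B = 200


def _as_sequences(sequences) -> list[str]:
    """Accept a CoreGenome, a single string, or an iterable of strings."""
    if hasattr(sequences, "sequences"):  # CoreGenome duck type
        return list(sequences.sequences)
    if isinstance(sequences, str):
        return [sequences]
    return list(sequences)


@dataclass
class MarkovModel:
    """Order-m Markov null model summarised by its k-mer counts.

    counts_m holds the 4^m context counts (for m=0 a single entry: the
    total number of 1-mer windows, i.e. N(empty)); counts_m1 the
    4^(m+1) transition-window counts; counts_1 the mononucleotide
    counts used as the fallback distribution for unseen contexts.
    """

    order: int
    counts_m: np.ndarray
    counts_m1: np.ndarray
    counts_1: np.ndarray
    train_lengths: list[int]

    @property
    def total_windows(self) -> dict[int, int]:
        tw = {1: int(self.counts_1.sum())}
        if self.order >= 1:
            tw[self.order] = int(self.counts_m.sum())
        tw[self.order + 1] = int(self.counts_m1.sum())
        return tw

    @property
    def kmer_counts_m(self) -> dict[str, int]:
        if self.order == 0:
            return {"": int(self.counts_m[0])}
        return {
            index_to_word(i, self.order): int(c)
            for i, c in enumerate(self.counts_m)
            if c > 0
        }

    @property
    def kmer_counts_m1(self) -> dict[str, int]:
        return {
            index_to_word(i, self.order + 1): int(c)
            for i, c in enumerate(self.counts_m1)
            if c > 0
        }

    def transition_matrix(self) -> np.ndarray:
        """p(b | context) rows; unseen contexts fall back to order 0."""
        rows = self.counts_m1.reshape(-1, 4).astype(float)
        sums = rows.sum(axis=1)
        p1 = self.counts_1.astype(float)
        if p1.sum() == 0:
            raise ValueError("model has no training windows")
        p1 = p1 / p1.sum()
        out = np.empty_like(rows)
        seen = sums > 0
        out[seen] = rows[seen] / sums[seen, None]
        out[~seen] = p1
        return out

    def _trans_flat(self) -> np.ndarray:
        return np.cumsum(self.transition_matrix(), axis=1).ravel()

    def _init_cum(self) -> np.ndarray:
        if self.order == 0:
            return np.ones(1)
        w = self.counts_m.astype(float)
        if w.sum() == 0:
            raise ValueError("model has no context counts")
        return np.cumsum(w / w.sum())


@dataclass
class WordStatistic:
    """Observed/expected/sd/z of one word under one model order."""

    word: str
    model_order: int
    observed: int
    expected: float | None
    sd: float | None
    z: float | None
    evaluable: bool

    def passes(self, z_threshold: float) -> bool:
        return self.evaluable and self.z is not None and self.z >= z_threshold


def count_word(sequences, word: str) -> int:
    """Overlapping occurrences of `word`, summed across sequences.

    Windows never span sequence boundaries; windows containing N cannot
    match an ACGT word and are therefore skipped implicitly.
    """
    wcodes = encode_word(word)
    total = 0
    for seq in _as_sequences(sequences):
        codes = seq if isinstance(seq, np.ndarray) else encode(seq)
        total += int(count_word_codes(codes, wcodes))
    return total


def count_all_kmers(sequences, k: int) -> dict[str, int]:
    """Counts of every observed k-mer (valid windows only)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    seqs = _as_sequences(sequences)
    arr = np.zeros(4**k, dtype=np.int64)
    any_window = False
    for seq in seqs:
        codes = seq if isinstance(seq, np.ndarray) else encode(seq)
        if codes.size >= k:
            any_window = True
            arr += kmer_count_array(codes, k)
    if not any_window:
        warnings.warn(f"k={k} exceeds every sequence length; no windows")
        return {}
    return {
        index_to_word(i, k): int(c) for i, c in enumerate(arr) if c > 0
    }


def _kmer_counts_concat(codes_concat: np.ndarray, k: int) -> np.ndarray:
    return kmer_count_array(codes_concat, k)


def fit_markov(sequences, order: int) -> MarkovModel:
    """Fit an order-m model by counting m-mers and (m+1)-mers."""
    if not (0 <= order <= 6):
        raise ValueError("order must be in 0..6")
    seqs = _as_sequences(sequences)
    arrays = [s if isinstance(s, np.ndarray) else encode(s) for s in seqs]
    concat = concat_with_breaks(arrays)
    counts_1 = _kmer_counts_concat(concat, 1)
    counts_m1 = _kmer_counts_concat(concat, order + 1)
    if counts_m1.sum() == 0:
        raise ValueError(
            f"no valid length-{order + 1} windows in training sequences"
        )
    if order == 0:
        counts_m = np.array([counts_1.sum()], dtype=np.int64)
    elif order == 1:
        counts_m = counts_1
    else:
        counts_m = _kmer_counts_concat(concat, order)
    return MarkovModel(
        order=order,
        counts_m=counts_m,
        counts_m1=counts_m1,
        counts_1=counts_1,
        train_lengths=[a.size for a in arrays],
    )


def expected_count(model: MarkovModel, word: str) -> float | None:
    """Plug-in expected count of `word` under the fitted model.

    Returns None (non-evaluable) when any denominator count is zero.
    For h = m+1 the denominator product is empty and the formula
    degenerates to the observed (m+1)-mer count itself.
    """
    wcodes = encode_word(word)
    h = wcodes.size
    m = model.order
    if h < m + 1:
        raise ValueError(f"word length {h} < order + 1 = {m + 1}")
    num = 1.0
    for j in range(h - m):
        sub = word_to_index(wcodes[j : j + m + 1])
        num *= float(model.counts_m1[sub])
    den = 1.0
    for j in range(1, h - m):
        if m == 0:
            factor = float(model.counts_m[0])
        else:
            factor = float(model.counts_m[word_to_index(wcodes[j : j + m])])
        if factor == 0.0:
            return None
        den *= factor
    return num / den


def _check_lengths(lengths) -> np.ndarray:
    lengths = np.asarray(lengths, dtype=np.int64)
    if lengths.size == 0 or (lengths <= 0).any():
        raise ValueError("lengths must be positive")
    return lengths


def _n_uniforms(lengths: np.ndarray, m: int) -> int:
    return int(np.sum(np.maximum(lengths - m, 0)) + lengths.size)


def _simulate_codes(model: MarkovModel, lengths, rng) -> np.ndarray:
    lengths = _check_lengths(lengths)
    m = model.order
    u = rng.random(_n_uniforms(lengths, m))
    return simulate_concat(
        lengths, m, model._init_cum(), model._trans_flat(), u
    )


def simulate_from_model(
    model: MarkovModel, lengths: Sequence[int], seed: int
) -> list[str]:
    """Simulate sequences from the fitted chain, reproducibly.

    The first m symbols are drawn from the empirical m-mer
    distribution, then transitions are chained; contexts never seen in
    training fall back to the order-0 composition.
    """
    rng = np.random.default_rng(seed)
    concat = _simulate_codes(model, lengths, rng)
    out = []
    pos = 0
    for L in lengths:
        out.append(_codes.decode(concat[pos : pos + L]))
        pos += L + 1
    return out


def _null_count_moments(
    model: MarkovModel, h: int, lengths, B: int, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap mean and sd (ddof=1) of all 4^h word counts."""
    if B < 2:
        raise ValueError("need at least B=2 replicates")
    lengths = _check_lengths(lengths)
    m = model.order
    init_cum = model._init_cum()
    trans_flat = model._trans_flat()
    n_u = _n_uniforms(lengths, m)
    s = np.zeros(4**h)
    s2 = np.zeros(4**h)
    for _ in range(B):
        c = sim_count_all(
            lengths, m, init_cum, trans_flat, rng.random(n_u), h
        ).astype(float)
        s += c
        s2 += c * c
    mean = s / B
    var = np.maximum(s2 - B * mean**2, 0.0) / (B - 1)
    return mean, np.sqrt(var)


def null_distribution(
    model: MarkovModel,
    word_length: int,
    lengths: Sequence[int],
    B: int,
    seed: int,
) -> dict[str, tuple[float, float]]:
    """Per-word (mean, sd) of counts over B simulated replicates."""
    rng = np.random.default_rng(seed)
    mean, sd = _null_count_moments(model, word_length, lengths, B, rng)
    return {
        index_to_word(i, word_length): (float(mean[i]), float(sd[i]))
        for i in range(4**word_length)
    }


def _bootstrap_word_sd(
    model: MarkovModel, wcodes: np.ndarray, lengths, B: int, rng
) -> float:
    lengths = _check_lengths(lengths)
    m = model.order
    h = int(wcodes.size)
    target = word_to_index(wcodes)
    init_cum = model._init_cum()
    trans_flat = model._trans_flat()
    n_u = _n_uniforms(lengths, m)
    counts = np.empty(B)
    for b in range(B):
        counts[b] = sim_count_word(
            lengths, m, init_cum, trans_flat, rng.random(n_u), h, target
        )
    return float(np.std(counts, ddof=1))


def _stationary_word_prob(
    model: MarkovModel, wcodes: np.ndarray
) -> float | None:
    """Probability of observing the word at a fixed position under the
    fitted chain started from the empirical context distribution."""
    m = model.order
    tw1 = float(model.counts_1.sum())
    if m == 0:
        p = 1.0
        for c in wcodes:
            p *= model.counts_1[int(c)] / tw1
        return p
    ctx_tot = float(model.counts_m.sum())
    p = model.counts_m[word_to_index(wcodes[:m])] / ctx_tot
    rows = model.counts_m1.reshape(-1, 4).astype(float)
    p1 = model.counts_1 / tw1
    for j in range(wcodes.size - m):
        ctx = word_to_index(wcodes[j : j + m])
        row = rows[ctx]
        rs = row.sum()
        if rs == 0:
            p *= p1[int(wcodes[j + m])]  # unseen context: order-0 fallback
        else:
            p *= row[int(wcodes[j + m])] / rs
    return float(p)


def _analytic_sd(model: MarkovModel, wcodes: np.ndarray, lengths) -> float:
    """Asymptotic sd of the word count with self-overlap corrections.

    Var(N) = sum over sequences of
        n mu (1-mu) + 2 sum_{d=1..h-1} (n-d) (P_d - mu^2)
    where n = L-h+1, mu the stationary word probability and P_d the
    joint probability of occurrences at lag d (nonzero only when the
    word overlaps itself at that lag).  Covariances at lags >= h decay
    with chain mixing and are neglected.
    """
    h = wcodes.size
    mu = _stationary_word_prob(model, wcodes)
    if mu is None:
        return float("nan")
    # joint probabilities at self-overlap lags
    pd_cache: dict[int, float] = {}
    for d in range(1, h):
        if np.array_equal(wcodes[d:], wcodes[: h - d]):
            merged = np.concatenate([wcodes, wcodes[h - d :]])
            pd_cache[d] = _stationary_word_prob(model, merged) or 0.0
    var = 0.0
    for L in lengths:
        n = L - h + 1
        if n <= 0:
            continue
        v = n * mu * (1.0 - mu)
        for d in range(1, min(h, n)):
            pd = pd_cache.get(d, 0.0)
            v += 2.0 * (n - d) * (pd - mu * mu)
        var += max(v, 0.0)
    return float(np.sqrt(var))


def zscore_word(
    core,
    word: str,
    order: int,
    method: str = "bootstrap",
    B: int = DEFAULT_B,
    seed: int = 0,
) -> WordStatistic:
    """Overrepresentation z-score of one word under one model order.

    The model is fitted on the same sequences being scored (plug-in,
    matching R'MES practice); counting is on the given strand only.
    """
    wcodes = encode_word(word)
    h = wcodes.size
    if order < 0 or h < order + 2:
        raise ValueError(
            f"order must satisfy 0 <= order <= {h - 2} for a length-{h} word"
        )
    if method not in ("bootstrap", "analytic"):
        raise ValueError("method must be 'bootstrap' or 'analytic'")
    seqs = _as_sequences(core)
    arrays = [s if isinstance(s, np.ndarray) else encode(s) for s in seqs]
    observed = sum(int(count_word_codes(a, wcodes)) for a in arrays)
    model = fit_markov(arrays, order)
    expected = expected_count(model, word)
    if expected is None:
        return WordStatistic(word, order, observed, None, None, None, False)
    lengths = [a.size for a in arrays]
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        sd = _bootstrap_word_sd(model, wcodes, lengths, B, rng)
    else:
        sd = _analytic_sd(model, wcodes, lengths)
    if not np.isfinite(sd) or sd == 0.0:
        return WordStatistic(word, order, observed, expected, sd, None, False)
    z = (observed - expected) / sd
    return WordStatistic(word, order, observed, expected, sd, float(z), True)


def score_all_models(
    core,
    word: str,
    orders: Iterable[int] = DEFAULT_ORDERS,
    method: str = "bootstrap",
    B: int = DEFAULT_B,
    seed: int = 0,
) -> list[WordStatistic]:
    """One WordStatistic per model order for the same word.

    All statistics share the observed count; per-order randomness is
    derived deterministically from `seed`.
    """
    orders = list(orders)
    child_seeds = np.random.SeedSequence(seed).spawn(len(orders))
    stats = []
    for o, ss in zip(orders, child_seeds):
        stats.append(
            zscore_word(
                core,
                word,
                o,
                method=method,
                B=B,
                seed=ss,
            )
        )
    return stats
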