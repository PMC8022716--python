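"""Nucleotide code arrays and compiled kernels shared across modules.

Sequences are represented internally as int8 arrays with A=0, C=1, G=2,
T=3 and N=-1.  Concatenating several sequences with a single -1 break
between them lets every windowed operation (k-mer counting, word search)
respect sequence boundaries for free: any window containing a negative
code is invalid, exactly like a window containing N.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BASES = "ACGT"

_LUT = np.full(256, -2, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i
for _c in "Nn":
    _LUT[ord(_c)] = -1
# RNA input is tolerated at this level; io normalises U->T on load anyway.
_LUT[ord("U")] = 3
_LUT[ord("u")] = 3


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to int8 codes (N -> -1)."""
    try:
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    except UnicodeEncodeError as exc:
        raise ValueError(f"non-ASCII character in sequence: {exc}") from None
    codes = _LUT[raw]
    bad = codes == -2
    if bad.any():
        pos = int(np.argmax(bad))
        raise ValueError(
            f"illegal nucleotide {seq[pos]!r} at position {pos + 1}"
        )
    return codes


def encode_word(word: str) -> np.ndarray:
    """Encode a word that must be strictly over {A,C,G,T}."""
    codes = encode(word)
    if codes.size == 0:
        raise ValueError("empty word")
    if (codes < 0).any():
        pos = int(np.argmax(codes < 0))
        raise ValueError(
            f"word {word!r} contains non-ACGT symbol at position {pos + 1}"
        )
    return codes


_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def decode(codes: np.ndarray) -> str:
    """Decode int8 codes back to a string (negative codes -> N)."""
    out = np.where(codes >= 0, _DECODE[np.clip(codes, 0, 3)], ord("N"))
    return out.astype(np.uint8).tobytes().decode("ascii")


def concat_with_breaks(code_arrays: list[np.ndarray]) -> np.ndarray:
    """Concatenate code arrays with a single -1 break between each pair."""
    arrays = list(code_arrays)
    if not arrays:
        return np.empty(0, dtype=np.int8)
    n_breaks = len(arrays) - 1
    total = sum(a.size for a in arrays) + n_breaks
    out = np.full(total, -1, dtype=np.int8)
    pos = 0
    for i, a in enumerate(arrays):
        out[pos : pos + a.size] = a
        pos += a.size + 1
    return out


def window_index(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 index of every length-k window plus a validity mask.

    Windows containing any negative code (N or sequence break) are
    flagged invalid; their index value is meaningless.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        valid &= c >= 0
        idx = (idx << 2) | np.where(c >= 0, c, 0).astype(np.int64)
    return idx, valid


def kmer_count_array(codes: np.ndarray, k: int) -> np.ndarray:
    """Counts of all 4^k words over valid windows, as a flat array."""
    idx, valid = window_index(codes, k)
    if idx.size == 0:
        return np.zeros(4**k, dtype=np.int64)
    return np.bincount(idx[valid], minlength=4**k).astype(np.int64)


def word_to_index(word_codes: np.ndarray) -> int:
    """Base-4 integer index of an ACGT word given as codes."""
    idx = 0
    for c in word_codes:
        idx = (idx << 2) | int(c)
    return idx


def index_to_word(idx: int, k: int) -> str:
    return "".join(BASES[(idx >> (2 * (k - 1 - j))) & 3] for j in range(k))


@njit(cache=True)
def count_word_codes(codes, word):  # pragma: no cover - exercised via wrappers
    """Number of exact (overlapping) matches of `word` in `codes`."""
    h = word.size
    n = 0
    for i in range(codes.size - h + 1):
        hit = True
        for j in range(h):
            if codes[i + j] != word[j]:
                hit = False
                break
        if hit:
            n += 1
    return n


@njit(cache=True)
def simulate_concat(lengths, m, init_cum, trans_flat, u):  # pragma: no cover
    """Simulate an order-m Markov chain per sequence, -1 breaks between.

    lengths   : int64 array of sequence lengths
    init_cum  : cumulative distribution over 4^m initial contexts
    trans_flat: flattened (4^m, 4) cumulative transition rows
    u         : uniforms, one per initial draw plus one per transition
                (sum over genes of 1 + max(0, L - m))
    """
    n_seq = lengths.size
    total = 0
    for g in range(n_seq):
        total += lengths[g]
    total += n_seq - 1
    out = np.full(total, np.int8(-1))
    cmask = init_cum.size - 1  # 4^m - 1
    pos = 0
    ui = 0
    for g in range(n_seq):
        if g > 0:
            pos += 1  # break slot stays -1
        L = lengths[g]
        uu = u[ui]
        ui += 1
        c = np.searchsorted(init_cum, uu, side="right")
        if c >= init_cum.size:
            c = init_cum.size - 1
        nwrite = L if L < m else m
        for j in range(nwrite):
            out[pos + j] = np.int8((c >> (2 * (m - 1 - j))) & 3)
        if L <= m:
            pos += L
            continue
        pos += m
        ctx = c
        for _t in range(L - m):
            uu = u[ui]
            ui += 1
            base = ctx << 2
            b = (
                np.int64(uu >= trans_flat[base])
                + np.int64(uu >= trans_flat[base + 1])
                + np.int64(uu >= trans_flat[base + 2])
            )
            out[pos] = np.int8(b)
            pos += 1
            ctx = (base | b) & cmask
    return out


@njit(cache=True)
def sim_count_all(lengths, m, init_cum, trans_flat, u, h):  # pragma: no cover
    """Simulate the chain and count all 4^h words in one fused pass.

    Bootstrap replicates never need the sequence itself, only its word
    counts; fusing the two avoids materializing megabase arrays.  A
    rolling base-4 window index is updated per emitted symbol and the
    count bumped once h symbols of the current sequence are in view.
    """
    nk = 1 << (2 * h)
    counts = np.zeros(nk, dtype=np.int64)
    kmask = nk - 1
    cmask = init_cum.size - 1
    ui = 0
    for g in range(lengths.size):
        L = lengths[g]
        uu = u[ui]
        ui += 1
        c = np.searchsorted(init_cum, uu, side="right")
        if c >= init_cum.size:
            c = init_cum.size - 1
        widx = 0
        filled = 0
        nwrite = L if L < m else m
        for j in range(nwrite):
            b = (c >> (2 * (m - 1 - j))) & 3
            widx = ((widx << 2) | b) & kmask
            filled += 1
            if filled >= h:
                counts[widx] += 1
        if L <= m:
            continue
        ctx = c
        for _t in range(L - m):
            uu = u[ui]
            ui += 1
            base = ctx << 2
            b = (
                np.int64(uu >= trans_flat[base])
                + np.int64(uu >= trans_flat[base + 1])
                + np.int64(uu >= trans_flat[base + 2])
            )
            ctx = (base | b) & cmask
            widx = ((widx << 2) | b) & kmask
            filled += 1
            if filled >= h:
                counts[widx] += 1
    return counts


@njit(cache=True)
def sim_count_word(
    lengths, m, init_cum, trans_flat, u, h, target
):  # pragma: no cover
    """Fused simulate-and-count for a single word index."""
    kmask = (1 << (2 * h)) - 1
    cmask = init_cum.size - 1
    n = 0
    ui = 0
    for g in range(lengths.size):
        L = lengths[g]
        uu = u[ui]
        ui += 1
        c = np.searchsorted(init_cum, uu, side="right")
        if c >= init_cum.size:
            c = init_cum.size - 1
        widx = 0
        filled = 0
        nwrite = L if L < m else m
        for j in range(nwrite):
            b = (c >> (2 * (m - 1 - j))) & 3
            widx = ((widx << 2) | b) & kmask
            filled += 1
            if filled >= h and widx == target:
                n += 1
        if L <= m:
            continue
        ctx = c
        for _t in range(L - m):
            uu = u[ui]
            ui += 1
            base = ctx << 2
            b = (
                np.int64(uu >= trans_flat[base])
                + np.int64(uu >= trans_flat[base + 1])
                + np.int64(uu >= trans_flat[base + 2])
            )
            ctx = (base | b) & cmask
            widx = ((widx << 2) | b) & kmask
            filled += 1
            if filled >= h and widx == target:
                n += 1
    return n
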