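"""Candidate motif sets: Hamming neighborhoods, mismatch expansions,
GC content, degenerate consensus and submotif enrichment.

Chi-like motif searches start from a seed octamer (GCTGGTGG in
E. coli) and widen to its mutational neighborhood; these operations
generate and characterise those candidate sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ALPHABET = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# nucleotide set -> IUPAC one-letter code
_IUPAC = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


def _check_acgt(word: str, what: str = "motif") -> str:
    w = word.upper()
    if not w or any(c not in ALPHABET for c in w):
        raise ValueError(f"{what} {word!r} must be a non-empty ACGT string")
    return w


@dataclass
class MotifSet:
    """A set of equal-length candidate motifs plus its provenance."""

    seeds: list[str]
    members: set[str]
    generation_rule: str = ""

    def __post_init__(self) -> None:
        if self.members:
            lengths = {len(m) for m in self.members}
            if len(lengths) != 1:
                raise ValueError("motif set members must share one length")
            for m in self.members:
                _check_acgt(m)

    def as_list(self) -> list[str]:
        """Members in deterministic lexicographic order."""
        return sorted(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.as_list())

    def __contains__(self, word: str) -> bool:
        return word in self.members


def reverse_complement(word: str) -> str:
    """Reverse complement over the ACGTN alphabet (involution)."""
    w = word.upper()
    if any(c not in "ACGTN" for c in w):
        bad = next(c for c in w if c not in "ACGTN")
        raise ValueError(f"illegal character {bad!r} in {word!r}")
    return w.translate(_COMPLEMENT)[::-1]


def hamming_distance(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("words must have equal length")
    return sum(x != y for x, y in zip(a, b))


def hamming_neighborhood(
    seed: str, radius: int, include_seed: bool = True
) -> MotifSet:
    """All words within Hamming distance `radius` of `seed`.

    With ``include_seed=False`` the seed itself (distance 0) is
    dropped, leaving distances 1..radius.
    """
    seed = _check_acgt(seed, "seed")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    members: set[str] = {seed} if include_seed else set()
    h = len(seed)
    for d in range(1, min(radius, h) + 1):
        for positions in itertools.combinations(range(h), d):
            choices = [[c for c in ALPHABET if c != seed[p]] for p in positions]
            for subst in itertools.product(*choices):
                w = list(seed)
                for p, c in zip(positions, subst):
                    w[p] = c
                members.add("".join(w))
    rule = f"hamming<= {radius} of {seed}" + (
        "" if include_seed else " (seed excluded)"
    )
    return MotifSet(seeds=[seed], members=members, generation_rule=rule)


def expand_two_mismatch(
    seeds: list[str], exclude: set[str] | frozenset[str] = frozenset()
) -> MotifSet:
    """Exact-distance-2 expansion of a seed list, ball-excluded.

    Returns the union over seeds of words at Hamming distance exactly 2,
    minus `exclude` and minus every word within distance <= 1 of ANY
    seed, so each member is at distance >= 2 from every seed and exactly
    2 from at least one.
    """
    if not seeds:
        raise ValueError("seeds must be non-empty")
    seeds = [_check_acgt(s, "seed") for s in seeds]
    near: set[str] = set()
    for s in seeds:
        near |= hamming_neighborhood(s, 1, include_seed=True).members
    members: set[str] = set()
    for s in seeds:
        sphere = hamming_neighborhood(s, 2, include_seed=True).members
        members |= {w for w in sphere if hamming_distance(w, s) == 2}
    members -= near
    members -= {w.upper() for w in exclude}
    rule = f"distance-2 expansion of {len(seeds)} seeds, ball-excluded"
    return MotifSet(seeds=list(seeds), members=members, generation_rule=rule)


def gc_content(sequence: str) -> float:
    """G+C fraction over informative (A,C,G,T) positions; N ignored."""
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    gc = sum(1 for c in seq if c in "GC")
    informative = sum(1 for c in seq if c in ALPHABET)
    if informative == 0:
        raise ValueError("sequence has no ACGT characters")
    return gc / informative


def degenerate_consensus(motifs: list[str]) -> str:
    """Per-column IUPAC code covering exactly the observed nucleotides."""
    if not motifs:
        raise ValueError("need at least one motif")
    ups = [_check_acgt(m) for m in motifs]
    if len({len(m) for m in ups}) != 1:
        raise ValueError("motifs must have equal length")
    out = []
    for col in zip(*ups):
        out.append(_IUPAC[frozenset(col)])
    return "".join(out)


def submotif_enrichment(
    motifs: list[str],
    k: int,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Enrichment of k-mers within a motif list vs column-shuffled nulls.

    Observed: overlapping occurrences of each k-mer across the motif
    list.  Expected: mean count when the residues of each alignment
    column are independently shuffled across motifs (preserving the
    per-column composition).  Rows sorted by ratio descending.
    """
    if not motifs:
        raise ValueError("need at least one motif")
    ups = [_check_acgt(m) for m in motifs]
    h = len(ups[0])
    if len({len(m) for m in ups}) != 1:
        raise ValueError("motifs must have equal length")
    if k > h:
        raise ValueError("k must not exceed the motif length")

    def _count(rows: list[str]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in rows:
            for i in range(h - k + 1):
                w = r[i : i + k]
                counts[w] = counts.get(w, 0) + 1
        return counts

    observed = _count(ups)
    rng = np.random.default_rng(seed)
    cols = np.array([list(m) for m in ups])  # (n_motifs, h)
    acc: dict[str, float] = {w: 0.0 for w in observed}
    for _ in range(n_shuffles):
        shuf = cols.copy()
        for j in range(h):
            shuf[:, j] = rng.permutation(shuf[:, j])
        for w, c in _count(["".join(r) for r in shuf]).items():
            acc[w] = acc.get(w, 0.0) + c
    rows = []
    for w, obs in observed.items():
        exp = acc.get(w, 0.0) / n_shuffles
        ratio = obs / exp if exp > 0 else np.inf
        rows.append((w, obs, exp, ratio))
    df = pd.DataFrame(rows, columns=["kmer", "observed", "expected", "ratio"])
    df = df.sort_values(
        ["ratio", "observed", "kmer"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return df
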