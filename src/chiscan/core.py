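"""Pseudo core genomes: genes shared with the two closest relatives.

Most bacterial species have too few sequenced strains for a true core
genome, so the core is approximated by the genes of a species that
have a best-reciprocal-hit ortholog in BOTH of its two phylogenetically
closest species.  Closeness comes from p-distances on a trimmed
concatenated marker alignment (or a user-supplied distance matrix);
orthology from global protein alignment with identity and length
conservation thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

__all__ = [
    "MarkerAlignment",
    "DistanceMatrix",
    "CoreGenome",
    "filter_alignment_columns",
    "pairwise_distance_matrix",
    "closest_relatives",
    "best_reciprocal_hits",
    "build_pseudo_core",
]

DEFAULT_MIN_IDENTITY = 0.70
DEFAULT_MIN_LENGTH_CONSERVATION = 0.80
DEFAULT_MAX_GAP_FRACTION = 0.5

# fixed, explicit global-alignment scoring (the contract requires a
# deterministic aligner, not any particular heuristic tool)
DEFAULT_SCORING = dict(
    match_score=1.0,
    mismatch_score=-1.0,
    open_gap_score=-5.0,
    extend_gap_score=-1.0,
)


@dataclass
class MarkerAlignment:
    """Concatenated marker alignment: equal-length protein rows."""

    species_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.species_ids) < 2:
            raise ValueError("alignment needs at least 2 species")
        if len(self.species_ids) != len(self.rows):
            raise ValueError("one row per species required")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative species-by-species distances."""

    species_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.species_ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match species count")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.diag(v).any():
            raise ValueError("diagonal must be exactly zero")
        if (v < 0).any():
            raise ValueError("distances must be nonnegative")
        self.values = v

    def get(self, a: str, b: str) -> float:
        ia = self.species_ids.index(a)
        ib = self.species_ids.index(b)
        return float(self.values[ia, ib])


@dataclass
class CoreGenome:
    """Per-species pseudo core: genes shared with both neighbors."""

    species_id: str
    neighbor_ids: tuple[str, str]
    genes: list[tuple[str, str]]  # (gene_id, coding-strand nt sequence)

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.genes]

    @property
    def sequences(self) -> list[str]:
        return [s for _, s in self.genes]

    def __len__(self) -> int:
        return len(self.genes)


def filter_alignment_columns(
    alignment: MarkerAlignment,
    max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION,
) -> MarkerAlignment:
    """Keep columns whose gap fraction is <= max_gap_fraction.

    A plain per-column filter standing in for heavier alignment
    trimmers; the downstream distance ranking is what matters.
    """
    if not (0.0 <= max_gap_fraction <= 1.0):
        raise ValueError("max_gap_fraction must be in [0, 1]")
    mat = np.array([list(r) for r in alignment.rows])
    if mat.size == 0:
        raise ValueError("empty alignment")
    gap_frac = (mat == "-").mean(axis=0)
    keep = gap_frac <= max_gap_fraction
    if not keep.any():
        warnings.warn("all alignment columns removed by gap filter")
        return MarkerAlignment(
            species_ids=list(alignment.species_ids),
            rows=["" for _ in alignment.rows],
        )
    rows = ["".join(row) for row in mat[:, keep]]
    return MarkerAlignment(
        species_ids=list(alignment.species_ids), rows=rows
    )


def pairwise_distance_matrix(alignment: MarkerAlignment) -> DistanceMatrix:
    """p-distances: mismatches over columns where neither row is gapped.

    Pairs with zero comparable columns get distance 1 and a warning.
    """
    mat = np.array([list(r) for r in alignment.rows])
    n = len(alignment.species_ids)
    values = np.zeros((n, n))
    gaps = mat == "-"
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ~gaps[i] & ~gaps[j]
            n_comp = int(comparable.sum())
            if n_comp == 0:
                warnings.warn(
                    f"no comparable columns between "
                    f"{alignment.species_ids[i]} and "
                    f"{alignment.species_ids[j]}; distance set to 1"
                )
                d = 1.0
            else:
                mism = int((mat[i][comparable] != mat[j][comparable]).sum())
                d = mism / n_comp
            values[i, j] = values[j, i] = d
    return DistanceMatrix(
        species_ids=list(alignment.species_ids), values=values
    )


def closest_relatives(
    matrix: DistanceMatrix, species: str, k: int
) -> list[str]:
    """The k nearest species, ascending by distance then label."""
    if species not in matrix.species_ids:
        raise KeyError(f"unknown species {species!r}")
    others = [s for s in matrix.species_ids if s != species]
    if k > len(others):
        raise ValueError(
            f"k={k} exceeds the {len(others)} other species available"
        )
    ranked = sorted(others, key=lambda s: (matrix.get(species, s), s))
    return ranked[:k]


def _make_aligner(scoring: dict | None = None) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    for key, val in {**DEFAULT_SCORING, **(scoring or {})}.items():
        setattr(aligner, key, val)
    return aligner


def global_identity(
    a: str, b: str, aligner: Align.PairwiseAligner | None = None
) -> float:
    """Identity of the optimal global alignment: matches over the full
    alignment length, gap columns included in the denominator."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = aligner or _make_aligner()
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def best_reciprocal_hits(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_length_conservation: float = DEFAULT_MIN_LENGTH_CONSERVATION,
    scoring: dict | None = None,
) -> list[tuple[str, str]]:
    """Orthologs as best reciprocal hits under global alignment.

    A pair (a, b) is returned iff each is the other's best hit by
    global-alignment identity, identity >= min_identity, and
    min(len)/max(len) >= min_length_conservation.  Best-hit ties break
    lexicographically; identities are computed once per unordered pair
    so the relation is symmetric by construction.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("proteomes must be non-empty")
    aligner = _make_aligner(scoring)
    ids_a = sorted(proteome_a)
    ids_b = sorted(proteome_b)
    ident = np.zeros((len(ids_a), len(ids_b)))
    for i, ia in enumerate(ids_a):
        for j, jb in enumerate(ids_b):
            ident[i, j] = global_identity(
                proteome_a[ia], proteome_b[jb], aligner
            )
    # argmax with lexicographic tie-break: ids are sorted, first max wins
    best_a = ident.argmax(axis=1)  # for each a, best b
    best_b = ident.argmax(axis=0)  # for each b, best a
    pairs: list[tuple[str, str]] = []
    for i, ia in enumerate(ids_a):
        j = int(best_a[i])
        if int(best_b[j]) != i:
            continue
        if ident[i, j] < min_identity:
            continue
        la, lb = len(proteome_a[ia]), len(proteome_b[ids_b[j]])
        if min(la, lb) / max(la, lb) < min_length_conservation:
            continue
        pairs.append((ia, ids_b[j]))
    return sorted(pairs)


def build_pseudo_core(
    species: str,
    gene_seqs: dict[str, str],
    proteome: dict[str, str],
    neighbor_proteomes: dict[str, dict[str, str]],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_length_conservation: float = DEFAULT_MIN_LENGTH_CONSERVATION,
    scoring: dict | None = None,
) -> CoreGenome:
    """Genes with a reciprocal ortholog in BOTH neighbor species.

    `neighbor_proteomes` maps the two neighbor species ids to their
    protein sets.  Returns the core carrying nucleotide sequences; an
    empty intersection is allowed (with a warning).
    """
    if set(gene_seqs) != set(proteome):
        raise ValueError(
            "gene ids differ between gene_seqs and proteome"
        )
    if len(neighbor_proteomes) != 2:
        raise ValueError("exactly two neighbor proteomes required")
    hit_sets = []
    hits_by_neighbor: dict[str, dict[str, str]] = {}
    for nid, nprot in neighbor_proteomes.items():
        pairs = best_reciprocal_hits(
            proteome,
            nprot,
            min_identity=min_identity,
            min_length_conservation=min_length_conservation,
            scoring=scoring,
        )
        hits_by_neighbor[nid] = dict(pairs)
        hit_sets.append({a for a, _ in pairs})
    shared = sorted(hit_sets[0] & hit_sets[1])
    if not shared:
        warnings.warn(
            f"empty pseudo core for {species}: no genes shared with both "
            "neighbors"
        )
    neighbor_ids = tuple(neighbor_proteomes.keys())
    core = CoreGenome(
        species_id=species,
        neighbor_ids=(neighbor_ids[0], neighbor_ids[1]),
        genes=[(g, gene_seqs[g]) for g in shared],
    )
    core.neighbor_hits = hits_by_neighbor  # type: ignore[attr-defined]
    return core
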