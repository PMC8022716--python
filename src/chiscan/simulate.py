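"""Synthetic genomes, planted polarized motifs, and species trios.

The generator emulates the study conditions the detection pipeline is
built for: Markov backgrounds with configurable GC content, a Chi-like
octamer planted at about one site per 5 kb whose strand follows the
leading strand of replication (switching at ori and ter), and trios of
related species whose genes diverge to controlled identity for
core-genome recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import _codes
from .io import (
    GeneFeature,
    GenomeRecord,
    write_fasta_mapping,
    write_gene_features,
    write_genome_fasta,
)
from .motifs import reverse_complement
from .words import fit_markov, simulate_from_model

__all__ = [
    "SyntheticTruth",
    "SpeciesSim",
    "simulate_genome",
    "plant_polarized_motifs",
    "simulate_species_trio",
    "make_toy_dataset",
]

# sense codons (standard table 11-ish usage: no TAA/TAG/TGA)
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass
class SyntheticTruth:
    """Ground truth for a genome with planted motif occurrences."""

    motif: str
    planted: list[tuple[int, str]]  # (1-based position, strand)
    ori: int
    ter: int
    target_density: float  # occurrences per kb
    polarization_level: float

    @property
    def n_planted(self) -> int:
        return len(self.planted)


@dataclass
class SpeciesSim:
    """One simulated species: genome, features, gene and protein sets."""

    species_id: str
    genome: GenomeRecord
    features: list[GeneFeature]
    gene_seqs: dict[str, str]
    proteins: dict[str, str]


def simulate_genome(
    length: int,
    gc: float = 0.5,
    order: int = 0,
    template: str | None = None,
    seed: int = 0,
    species_id: str = "sim",
    replicon_id: str = "chr",
    circular: bool = True,
) -> GenomeRecord:
    """Random genome from an order-m Markov background.

    Order 0 draws i.i.d. bases with p(G)=p(C)=gc/2; higher orders fit a
    model on `template` and simulate from it.  Reproducible given seed.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    if order == 0 and template is None:
        if not (0.0 < gc < 1.0):
            raise ValueError("gc must be strictly between 0 and 1")
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        cum = np.cumsum(p)
        codes = np.searchsorted(cum, rng.random(length), side="right")
        seq = _codes.decode(codes.astype(np.int8))
    else:
        if template is None:
            raise ValueError("order > 0 requires a template sequence")
        model = fit_markov([template], order)
        (seq,) = simulate_from_model(
            model, [length], seed=int(rng.integers(2**31))
        )
    return GenomeRecord(
        species_id=species_id,
        replicon_id=replicon_id,
        sequence=seq,
        circular=circular,
    )


def _on_forward_leading_arc(pos: int, ori: int, ter: int, length: int) -> bool:
    """True if `pos` lies on the ori->ter arc walked in increasing
    coordinates (the replichore whose leading strand is the forward
    strand)."""
    if ori < ter:
        return ori <= pos < ter
    return pos >= ori or pos < ter


def plant_polarized_motifs(
    genome: GenomeRecord,
    motif: str,
    density: float,
    ori: int,
    ter: int,
    polarization_level: float,
    seed: int = 0,
    max_rounds: int = 100,
) -> tuple[GenomeRecord, SyntheticTruth]:
    """Overwrite the background with polarized motif occurrences.

    The number of sites is Poisson(length/1000 * density); positions
    are uniform and non-overlapping.  Each site goes on the leading
    strand of its replichore with probability `polarization_level`
    (forward strand on the ori->ter arc, reverse complement on the
    other arc), otherwise on the lagging strand.  Planting overwrites
    in place so genome length and ori/ter geometry are untouched.
    """
    if ori == ter:
        raise ValueError("ori and ter must differ")
    if not (0.5 <= polarization_level <= 1.0):
        raise ValueError("polarization_level must be in [0.5, 1]")
    L = len(genome)
    lam = L / 1000.0 * density
    if lam < 1:
        raise ValueError("density * length too small: expect >= 1 site")
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(lam))
    h = len(motif)
    codes = _codes.encode(genome.sequence)
    fwd = _codes.encode_word(motif)
    rev = _codes.encode_word(reverse_complement(motif))
    occupied = np.zeros(L, dtype=bool)
    placed: list[int] = []
    rounds = 0
    while len(placed) < n:
        rounds += 1
        if rounds > max_rounds:
            raise ValueError(
                "could not place non-overlapping sites; density too high"
            )
        need = n - len(placed)
        cands = rng.integers(1, L - h + 2, size=max(2 * need, 16))
        for p in cands:
            if len(placed) >= n:
                break
            lo = int(p) - 1
            if occupied[lo : lo + h].any():
                continue
            occupied[lo : lo + h] = True
            placed.append(int(p))
    planted: list[tuple[int, str]] = []
    for p in sorted(placed):
        leading_forward = _on_forward_leading_arc(p, ori, ter, L)
        on_leading = rng.random() < polarization_level
        plus = leading_forward if on_leading else not leading_forward
        codes[p - 1 : p - 1 + h] = fwd if plus else rev
        planted.append((p, "+" if plus else "-"))
    new_genome = GenomeRecord(
        species_id=genome.species_id,
        replicon_id=genome.replicon_id,
        sequence=_codes.decode(codes),
        circular=genome.circular,
    )
    truth = SyntheticTruth(
        motif=motif,
        planted=planted,
        ori=ori,
        ter=ter,
        target_density=density,
        polarization_level=polarization_level,
    )
    return new_genome, truth


def _mutate_gene(
    nt: str, identity: float, rng, max_retries: int = 100
) -> str:
    """Point-mutate a coding sequence to a target nucleotide identity,
    re-drawing codons whose mutations create internal stops."""
    codes = _codes.encode(nt).copy()
    mutate = rng.random(codes.size) < (1.0 - identity)
    shifts = rng.integers(1, 4, size=codes.size)
    out = codes.copy()
    out[mutate] = (codes[mutate] + shifts[mutate]) % 4
    n_codons = codes.size // 3
    for ci in range(n_codons):
        a, b = 3 * ci, 3 * ci + 3
        for _ in range(max_retries):
            codon = _codes.decode(out[a:b])
            if codon not in _STOPS:
                break
            m = mutate[a:b]
            sh = rng.integers(1, 4, size=3)
            out[a:b] = np.where(m, (codes[a:b] + sh) % 4, codes[a:b])
        else:
            out[a:b] = codes[a:b]  # revert: keep the ancestral codon
    return _codes.decode(out)


def _translate(nt: str) -> str:
    return str(Seq(nt).translate())


def simulate_species_trio(
    n_genes: int,
    gene_length: int,
    identities: tuple[float, float],
    seed: int = 0,
    spacer: int = 60,
) -> tuple[dict[str, SpeciesSim], pd.DataFrame]:
    """A focal species plus two relatives at controlled divergence.

    Ancestor genes are random sense codons; each relative derives from
    them by point mutations to the target nucleotide identity (internal
    stops re-drawn).  Returns the three species (genome + GFF-style
    features + gene and protein sets) and a truth table of per-gene
    realized nucleotide and protein identities for each neighbor.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if gene_length < 3:
        raise ValueError("gene_length must be >= 3")
    for ident in identities:
        if not (0.0 < ident <= 1.0):
            raise ValueError("identities must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_codons = gene_length // 3
    anc_genes: dict[str, str] = {}
    for gi in range(n_genes):
        codons = rng.choice(len(_SENSE_CODONS), size=n_codons)
        anc_genes[f"g{gi + 1:04d}"] = "".join(
            _SENSE_CODONS[c] for c in codons
        )

    species_ids = ["focal", "near1", "near2"]
    gene_sets = {"focal": anc_genes}
    truth_rows = []
    for sp, ident in zip(["near1", "near2"], identities):
        derived: dict[str, str] = {}
        for gid, nt in anc_genes.items():
            mut = _mutate_gene(nt, ident, rng)
            derived[gid] = mut
            nt_id = float(
                np.mean(_codes.encode(nt) == _codes.encode(mut))
            )
            p_anc, p_mut = _translate(nt), _translate(mut)
            prot_id = float(
                np.mean([a == b for a, b in zip(p_anc, p_mut)])
            )
            truth_rows.append((gid, sp, ident, nt_id, prot_id))
        gene_sets[sp] = derived

    out: dict[str, SpeciesSim] = {}
    for sp in species_ids:
        genes = gene_sets[sp]
        seq_parts: list[str] = []
        features: list[GeneFeature] = []
        pos = 1
        for gid, nt in genes.items():
            if spacer:
                sp_codes = rng.integers(0, 4, size=spacer).astype(np.int8)
                seq_parts.append(_codes.decode(sp_codes))
                pos += spacer
            seq_parts.append(nt)
            features.append(
                GeneFeature(gid, f"{sp}_chr", pos, pos + len(nt) - 1, "+")
            )
            pos += len(nt)
        genome = GenomeRecord(
            species_id=sp,
            replicon_id=f"{sp}_chr",
            sequence="".join(seq_parts),
            circular=False,
        )
        out[sp] = SpeciesSim(
            species_id=sp,
            genome=genome,
            features=features,
            gene_seqs=dict(genes),
            proteins={g: _translate(nt) for g, nt in genes.items()},
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene_id",
            "neighbor",
            "target_nt_identity",
            "nt_identity",
            "protein_identity",
        ],
    )
    return out, truth


_TOY_DEFAULTS = {
    "n_species_planted": 2,
    "n_species_null": 1,
    "genome_length": 200_000,
    "motif": "GCTGGTGG",
    "density_per_kb": 0.2,
    "polarization": 0.9,
    "gc": 0.5,
    "n_core_genes": 60,
    "core_gene_length": 1200,
}


def make_toy_dataset(config: dict | None, seed: int, out_dir) -> Path:
    """Write a small end-to-end fixture directory.

    Emits per-species genome FASTA + GFF3 + core FASTA, a marker
    alignment, a Newick tree and a truth TSV, so every pipeline step
    runs with no external data.  Unknown config keys and zero species
    raise.
    """
    cfg = dict(_TOY_DEFAULTS)
    if config:
        unknown = set(config) - set(_TOY_DEFAULTS)
        if unknown:
            raise ValueError(f"invalid config keys: {sorted(unknown)}")
        cfg.update(config)
    n_total = cfg["n_species_planted"] + cfg["n_species_null"]
    if n_total < 1:
        raise ValueError("config must request at least one species")
    out_dir = Path(out_dir)
    for sub in ("genomes", "features", "core"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    L = cfg["genome_length"]
    truth_rows = []
    species_names = [
        f"planted{i + 1:02d}" for i in range(cfg["n_species_planted"])
    ] + [f"null{i + 1:02d}" for i in range(cfg["n_species_null"])]

    # shared random marker protein; species copies lightly mutated
    marker_len = 400
    marker = "".join(
        rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=marker_len)
    )
    marker_rows = {}

    for sp in species_names:
        sp_seed = int(rng.integers(2**31))
        genome = simulate_genome(
            L,
            gc=cfg["gc"],
            seed=sp_seed,
            species_id=sp,
            replicon_id=f"{sp}_chr",
            circular=True,
        )
        if sp.startswith("planted"):
            genome, truth = plant_polarized_motifs(
                genome,
                cfg["motif"],
                cfg["density_per_kb"],
                ori=1,
                ter=L // 2,
                polarization_level=cfg["polarization"],
                seed=int(rng.integers(2**31)),
            )
            for pos, strand in truth.planted:
                truth_rows.append((sp, cfg["motif"], pos, strand))
        write_genome_fasta([genome], out_dir / "genomes" / f"{sp}.fna")

        glen = cfg["core_gene_length"]
        gap = max((L - cfg["n_core_genes"] * glen) // cfg["n_core_genes"], 1)
        features = []
        pos = 1
        for gi in range(cfg["n_core_genes"]):
            if pos + glen - 1 > L:
                break
            features.append(
                GeneFeature(
                    f"{sp}_g{gi + 1:04d}",
                    genome.replicon_id,
                    pos,
                    pos + glen - 1,
                    "+",
                )
            )
            pos += glen + gap
        write_gene_features(features, out_dir / "features" / f"{sp}.gff")
        core = {
            f.gene_id: genome.sequence[f.start - 1 : f.end]
            for f in features
        }
        write_fasta_mapping(core, out_dir / "core" / f"{sp}_core.fna")

        row = list(marker)
        n_mut = int(rng.integers(4, 12))
        for _ in range(n_mut):
            i = int(rng.integers(marker_len))
            row[i] = str(rng.choice(list("ACDEFGHIKLMNPQRSTVWY")))
        marker_rows[sp] = "".join(row)

    with open(out_dir / "markers.afa", "w") as fh:
        for sp, row in marker_rows.items():
            fh.write(f">{sp}\n{row}\n")
    newick = _ladder_newick(species_names)
    (out_dir / "tree.nwk").write_text(newick + "\n")
    pd.DataFrame(
        truth_rows, columns=["species", "motif", "position", "strand"]
    ).to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return out_dir


def _ladder_newick(names: list[str]) -> str:
    if len(names) == 1:
        return f"({names[0]});"
    tree = f"({names[0]},{names[1]})"
    for name in names[2:]:
        tree = f"({tree},{name})"
    return tree + ";"
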