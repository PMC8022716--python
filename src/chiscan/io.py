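"""Reading and writing the standard formats the pipeline touches.

Coordinates are 1-based inclusive (GFF3 native) everywhere; no
half-open conversion happens anywhere in the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import reverse_complement

__all__ = [
    "GenomeRecord",
    "GeneFeature",
    "read_genome_fasta",
    "write_genome_fasta",
    "read_fasta_mapping",
    "write_fasta_mapping",
    "read_gene_features",
    "write_gene_features",
    "extract_gene_sequences",
    "write_results_table",
]

_VALID = re.compile(r"^[ACGTN]*$")


@dataclass
class GenomeRecord:
    """One replicon: uppercase ACGTN sequence plus identity and shape."""

    species_id: str
    replicon_id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for replicon {self.replicon_id}")
        if not _VALID.match(self.sequence):
            pos = next(
                i for i, c in enumerate(self.sequence) if c not in "ACGTN"
            )
            raise ValueError(
                f"illegal nucleotide {self.sequence[pos]!r} at position "
                f"{pos + 1} in replicon {self.replicon_id}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    """A gene/CDS interval, 1-based inclusive, with strand."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"feature {self.gene_id}: need 1 <= start <= end, got "
                f"{self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"feature {self.gene_id}: unknown strand {self.strand!r}"
            )


def _normalise(seq: str, name: str) -> str:
    s = seq.upper().replace("U", "T")
    if not _VALID.match(s):
        pos = next(i for i, c in enumerate(s) if c not in "ACGTN")
        raise ValueError(
            f"illegal character {seq[pos]!r} at position {pos + 1} "
            f"in entry {name!r}"
        )
    return s


def read_genome_fasta(
    path, species_id: str | None = None, circular: bool = False
) -> list[GenomeRecord]:
    """Load replicons from FASTA; uppercased, U mapped to T.

    `species_id` defaults to the file stem; `circular` applies to all
    records (assemblies rarely annotate topology in plain FASTA).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    sp = species_id if species_id is not None else path.stem
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            GenomeRecord(
                species_id=sp,
                replicon_id=rec.id,
                sequence=_normalise(str(rec.seq), rec.id),
                circular=circular,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids = [r.replicon_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate replicon ids in {path}")
    return records


def write_genome_fasta(records: list[GenomeRecord], path) -> None:
    recs = [
        SeqRecord(Seq(r.sequence), id=r.replicon_id, description="")
        for r in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta_mapping(path) -> dict[str, str]:
    """FASTA -> {id: uppercase sequence}; for gene/protein sets."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta_mapping(mapping: dict[str, str], path) -> None:
    recs = [
        SeqRecord(Seq(s), id=name, description="")
        for name, s in mapping.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_gene_features(path, feature_kind: str = "CDS") -> list[GeneFeature]:
    """Parse GFF3 rows of one feature kind into GeneFeature records.

    Coordinates stay 1-based inclusive as in the file.  Rows of other
    kinds are ignored; malformed rows, end < start, and strands outside
    {+,-} raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    features: list[GeneFeature] = []
    auto = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(
                    f"{path}:{lineno}: GFF3 row has {len(cols)} columns, "
                    "expected 9"
                )
            seqid, _source, kind, start, end, _score, strand, _phase, attrs = (
                cols[:9]
            )
            if kind != feature_kind:
                continue
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValueError(
                    f"{path}:{lineno}: end {end_i} < start {start_i}"
                )
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}:{lineno}: unknown strand symbol {strand!r}"
                )
            gene_id = None
            for part in attrs.split(";"):
                if part.startswith("ID="):
                    gene_id = part[3:].strip()
                    break
            if not gene_id:
                auto += 1
                gene_id = f"{feature_kind}_{auto}"
            features.append(
                GeneFeature(gene_id, seqid, start_i, end_i, strand)
            )
    ids = [f.gene_id for f in features]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate gene ids in {path}")
    return features


def write_gene_features(features: list[GeneFeature], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.replicon_id}\tchiscan\tCDS\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t0\tID={f.gene_id}\n"
            )


def extract_gene_sequences(
    genomes: list[GenomeRecord], features: list[GeneFeature]
) -> dict[str, str]:
    """Coding-strand (5'->3') sequence of each feature.

    Minus-strand features are reverse complemented so every returned
    sequence reads in the direction of translation.
    """
    by_replicon = {g.replicon_id: g for g in genomes}
    out: dict[str, str] = {}
    for f in features:
        g = by_replicon.get(f.replicon_id)
        if g is None:
            raise KeyError(
                f"feature {f.gene_id}: replicon {f.replicon_id!r} not found"
            )
        if f.end > len(g):
            raise ValueError(
                f"feature {f.gene_id}: end {f.end} exceeds replicon "
                f"length {len(g)}"
            )
        sub = g.sequence[f.start - 1 : f.end]
        out[f.gene_id] = sub if f.strand == "+" else reverse_complement(sub)
    return out


def write_results_table(records: list[dict], path) -> None:
    """Write homogeneous result records as a TSV with a header row.

    Floats are rendered with 6 significant digits; rows keep input
    order.
    """
    path = Path(path)
    if records:
        keys = list(records[0].keys())
        for i, rec in enumerate(records):
            if list(rec.keys()) != keys:
                raise ValueError(
                    f"record {i} has keys {list(rec.keys())}, expected {keys}"
                )
        df = pd.DataFrame.from_records(records, columns=keys)
    else:
        df = pd.DataFrame()
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
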