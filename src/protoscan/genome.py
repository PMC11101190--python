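"""Genome sequences and strand-aware annotations.

A :class:`GenomeRecord` holds a named, linear-coordinate nucleotide sequence
together with its annotation set (protein-coding genes, RNA genes,
pseudogenes, repeat regions and IS elements).  All internal coordinates are
0-based, half-open; BED output keeps that convention, FASTA carries only the
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STRANDS = ("+", "-")

#: annotation kinds that count as repetitive sequence for window/region filters
REPEAT_KINDS = frozenset({"repeat", "IS"})
#: annotation kinds whose same-strand overlap excludes a candidate region
GENIC_KINDS = frozenset({"gene", "rna", "pseudogene"})


@dataclass(frozen=True)
class Feature:
    """A strand-aware annotated interval (0-based, half-open)."""

    name: str
    start: int
    end: int
    strand: str
    kind: str = "gene"

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r} for {self.name}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end}) for {self.name}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        """Number of bases shared with [start, end)."""
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class GenomeRecord:
    """A named linear genome with an annotation set."""

    name: str
    sequence: str
    features: list[Feature] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def features_of(self, *kinds: str) -> list[Feature]:
        want = set(kinds)
        return [f for f in self.features if f.kind in want]

    @property
    def genes(self) -> list[Feature]:
        return [f for f in self.features if f.kind in GENIC_KINDS]

    @property
    def coding_genes(self) -> list[Feature]:
        return self.features_of("gene")

    @property
    def repeats(self) -> list[Feature]:
        return [f for f in self.features if f.kind in REPEAT_KINDS]

    def subsequence(self, start: int, end: int, strand: str = "+") -> str:
        if not (0 <= start <= end <= self.length):
            raise ValueError(f"interval [{start}, {end}) outside genome of length {self.length}")
        seq = self.sequence[start:end]
        return seq if strand == "+" else reverse_complement(seq)

    # ------------------------------------------------------------------ I/O

    def write_fasta(self, path: str | Path) -> None:
        rec = SeqRecord(Seq(self.sequence), id=self.name, description="")
        SeqIO.write([rec], str(path), "fasta")

    def write_bed(self, path: str | Path) -> None:
        """BED6; the name column carries ``<name>|<kind>``."""
        with open(path, "w") as fh:
            for f in sorted(self.features, key=lambda f: (f.start, f.end)):
                fh.write(f"{self.name}\t{f.start}\t{f.end}\t{f.name}|{f.kind}\t0\t{f.strand}\n")

    @classmethod
    def from_fasta(cls, fasta: str | Path, bed: str | Path | None = None) -> "GenomeRecord":
        rec = next(SeqIO.parse(str(fasta), "fasta"))
        genome = cls(name=rec.id, sequence=str(rec.seq).upper())
        if bed is not None:
            genome.features = read_bed(bed)
        return genome


def read_bed(path: str | Path) -> list[Feature]:
    feats: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            name, _, kind = cols[3].partition("|")
            feats.append(
                Feature(
                    name=name,
                    start=int(cols[1]),
                    end=int(cols[2]),
                    strand=cols[5] if len(cols) > 5 else "+",
                    kind=kind or "gene",
                )
            )
    return feats


_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def with_features(genome: GenomeRecord, features: list[Feature]) -> GenomeRecord:
    return replace(genome, features=list(features))
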