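"""Reference genome container, FASTA I/O and exact substring mapping.

The mapper is a seed-and-verify exact matcher over both strands: desk-scale
replacement for a short-read aligner when reads are error-free junction
fragments.  Real, externally aligned data enters through SAM import instead
(:mod:`ty5cards.reads`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Genome:
    """An ordered collection of named chromosome sequences over {A,C,G,T}.

    Chromosome names are unique, sequences non-empty and upper-case.
    """

    chromosomes: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("chromosome names must be unique")
        for name, seq in self.chromosomes:
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")
            if not set(seq) <= VALID_BASES:
                raise ValueError(f"chromosome {name!r} contains non-ACGT characters")

    @classmethod
    def from_dict(cls, chroms: dict[str, str] | Iterable[tuple[str, str]]) -> "Genome":
        items = chroms.items() if isinstance(chroms, dict) else chroms
        return cls(tuple((n, s.upper()) for n, s in items))

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes}

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.chromosomes)

    def sequence(self, chrom: str) -> str:
        for name, seq in self.chromosomes:
            if name == chrom:
                return seq
        raise KeyError(f"unknown chromosome {chrom!r}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self.chromosomes
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        chroms = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
        if not chroms:
            raise ValueError(f"no sequences found in {path}")
        return cls.from_dict(chroms)


@dataclass
class GenomeIndex:
    """Exact-substring lookup over both strands of a genome.

    Seeds on fixed-length k-mers (k = ``seed_len``) and verifies full-length
    matches by direct comparison.  Queries shorter than the seed fall back to
    a linear scan, which only matters for pathological inputs.
    """

    genome: Genome
    seed_len: int = 12
    _seeds: dict[str, list[tuple[str, int]]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        k = self.seed_len
        for name, seq in self.genome.chromosomes:
            for i in range(len(seq) - k + 1):
                self._seeds.setdefault(seq[i : i + k], []).append((name, i))

    def occurrences(self, query: str, max_hits: int = 2) -> list[tuple[str, int, str]]:
        """All genomic occurrences of ``query`` as (chrom, start, strand).

        A minus-strand occurrence at (chrom, start) means the reverse
        complement of ``query`` appears on the plus strand at ``start``
        (0-based, half-open span of len(query)).  Stops early once
        ``max_hits`` occurrences are found.
        """
        if not query or not set(query) <= VALID_BASES:
            return []
        hits: list[tuple[str, int, str]] = []
        for strand, probe in (("+", query), ("-", revcomp(query))):
            if len(probe) >= self.seed_len:
                for chrom, i in self._seeds.get(probe[: self.seed_len], ()):
                    seq = self.genome.sequence(chrom)
                    if seq[i : i + len(probe)] == probe:
                        hits.append((chrom, i, strand))
                        if len(hits) >= max_hits:
                            return hits
            else:
                for chrom, seq in self.genome.chromosomes:
                    start = seq.find(probe)
                    while start != -1:
                        hits.append((chrom, start, strand))
                        if len(hits) >= max_hits:
                            return hits
                        start = seq.find(probe, start + 1)
        return hits


def scan_occurrences(genome: Genome, query: str) -> Iterator[tuple[str, int, str]]:
    """Brute-force both-strand scan; the independent oracle for GenomeIndex."""
    if not query or not set(query) <= VALID_BASES:
        return
    for strand, probe in (("+", query), ("-", revcomp(query))):
        for chrom, seq in genome.chromosomes:
            start = seq.find(probe)
            while start != -1:
                yield chrom, start, strand
                start = seq.find(probe, start + 1)
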