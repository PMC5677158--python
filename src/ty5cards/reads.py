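"""Junction-read processing: trim the Ty5 tag, map the genomic fragment,
and collapse unique mappings into deduplicated insertion events.

A calling-card read begins with the transposon terminal sequence (the tag)
followed by the genomic DNA flanking the integration junction.  After
trimming, the genomic fragment is placed on the reference by exact match
over both strands; reads that map to exactly one location become evidence
for an insertion event at the junction base.  Reads sharing a
(chrom, position, strand) key are one event with a read count — the
deduplication that separates independent integrations from inverse-PCR
amplification of a single event.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO

from .genome import Genome, GenomeIndex


class MapStatus(str, Enum):
    UNIQUE = "UNIQUE"
    MULTI = "MULTI"
    UNMAPPED = "UNMAPPED"
    NO_TAG = "NO_TAG"
    TOO_SHORT = "TOO_SHORT"


@dataclass(frozen=True)
class ReadRecord:
    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r} is empty")
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"read {self.id!r}: sequence/quality length mismatch")


@dataclass(frozen=True)
class MappingResult:
    read_id: str
    status: MapStatus
    chrom: str | None = None
    position: int | None = None  # 0-based insertion coordinate (junction base)
    strand: str | None = None
    digest: str | None = None

    def __post_init__(self) -> None:
        has_coords = self.chrom is not None and self.position is not None and self.strand is not None
        if self.status is MapStatus.UNIQUE and not has_coords:
            raise ValueError("UNIQUE mapping must carry coordinates")
        if self.status is not MapStatus.UNIQUE and (
            self.chrom is not None or self.position is not None or self.strand is not None
        ):
            raise ValueError(f"{self.status.value} mapping must not carry coordinates")


@dataclass(frozen=True)
class InsertionEvent:
    """One deduplicated Ty5 integration with its supporting-read count."""

    chrom: str
    position: int
    strand: str
    read_count: int
    digests: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class InsertionSet:
    """All insertion events of one construct library plus the RPM denominator.

    ``total_aligned_reads`` counts uniquely mapped reads — the library-size
    denominator used by reads-per-million normalization.
    """

    construct: str
    total_aligned_reads: int
    events: list[InsertionEvent] = field(default_factory=list)
    qc: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = {(e.chrom, e.position, e.strand) for e in self.events}
        if len(keys) != len(self.events):
            raise ValueError("duplicate (chrom, position, strand) event keys")
        if sum(e.read_count for e in self.events) > self.total_aligned_reads:
            raise ValueError("event read counts exceed total aligned reads")

    def __len__(self) -> int:
        return len(self.events)

    def positions(self) -> set[tuple[str, int, str]]:
        return {(e.chrom, e.position, e.strand) for e in self.events}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#construct={self.construct}\n")
            fh.write(f"#total_aligned_reads={self.total_aligned_reads}\n")
            fh.write("chrom\tposition\tstrand\tread_count\tdigests\n")
            for e in sorted(self.events, key=lambda x: (x.chrom, x.position, x.strand)):
                digests = ",".join(sorted(e.digests)) if e.digests else "."
                fh.write(f"{e.chrom}\t{e.position}\t{e.strand}\t{e.read_count}\t{digests}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InsertionSet":
        construct = ""
        total = 0
        events: list[InsertionEvent] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#construct="):
                    construct = line.split("=", 1)[1]
                elif line.startswith("#total_aligned_reads="):
                    total = int(line.split("=", 1)[1])
                elif line.startswith(("#", "chrom")):
                    continue
                elif line:
                    c, p, s, rc, dg = line.split("\t")
                    digests = frozenset() if dg == "." else frozenset(dg.split(","))
                    events.append(InsertionEvent(c, int(p), s, int(rc), digests))
        return cls(construct, total, events)

    def qc_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "construct": self.construct,
                    "total_aligned_reads": self.total_aligned_reads,
                    "n_events": len(self.events),
                    "status_counts": self.qc,
                },
                fh,
                indent=2,
            )


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        yield ReadRecord(rec.id, str(rec.seq).upper(), "".join(chr(q + 33) for q in quals))


def _hamming_within(a: str, b: str, limit: int) -> bool:
    mismatches = 0
    for x, y in zip(a, b):
        if x != y:
            mismatches += 1
            if mismatches > limit:
                return False
    return True


def trim_junction(
    read: ReadRecord,
    tag: str,
    max_mismatch: int = 0,
    min_frag: int = 18,
) -> tuple[MapStatus, str | None]:
    """Strip the transposon tag off the read prefix.

    Returns (UNIQUE, fragment) when the prefix matches the tag within
    ``max_mismatch`` Hamming distance and the remaining genomic fragment is
    at least ``min_frag`` bases; otherwise (NO_TAG, None) or
    (TOO_SHORT, None).  UNIQUE here only means "usable fragment" — mapping
    decides the final status.
    """
    if len(tag) < 8:
        raise ValueError("tag must be >= 8 bp")
    if not read.sequence:
        raise ValueError("empty read")
    if len(read.sequence) < len(tag):
        return MapStatus.NO_TAG, None
    if not _hamming_within(read.sequence[: len(tag)], tag, max_mismatch):
        return MapStatus.NO_TAG, None
    fragment = read.sequence[len(tag) :]
    if len(fragment) < min_frag:
        return MapStatus.TOO_SHORT, None
    return MapStatus.UNIQUE, fragment


def map_fragment(
    fragment: str, index: GenomeIndex, read_id: str = "", digest: str | None = None
) -> MappingResult:
    """Place a trimmed genomic fragment by exact match over both strands.

    The reported position is the junction base: for a plus-strand match, the
    first base of the fragment; for a minus-strand match, the plus-strand
    coordinate of the fragment's first base, which is the *end* of the
    matched span minus one.
    """
    hits = index.occurrences(fragment, max_hits=2)
    if not hits:
        return MappingResult(read_id, MapStatus.UNMAPPED)
    if len(hits) > 1:
        return MappingResult(read_id, MapStatus.MULTI)
    chrom, start, strand = hits[0]
    position = start if strand == "+" else start + len(fragment) - 1
    return MappingResult(read_id, MapStatus.UNIQUE, chrom, position, strand, digest)


def _digest_label(read_id: str) -> str | None:
    # simulator read names are "ins000123|HindIII|rep0"
    parts = read_id.split("|")
    return parts[1] if len(parts) == 3 else None


def map_reads(
    reads: Iterable[ReadRecord],
    index: GenomeIndex,
    tag: str,
    max_mismatch: int = 0,
    min_frag: int = 18,
) -> Iterator[MappingResult]:
    """Trim + map a read stream, preserving per-read digest labels."""
    for read in reads:
        status, fragment = trim_junction(read, tag, max_mismatch, min_frag)
        if status is not MapStatus.UNIQUE:
            yield MappingResult(read.id, status)
            continue
        yield map_fragment(fragment, index, read.id, _digest_label(read.id))


def call_insertions(
    mappings: Iterable[MappingResult], construct: str = "construct"
) -> InsertionSet:
    """Collapse unique mappings into deduplicated insertion events.

    Events are keyed by (chrom, position, strand); read_count is the number
    of unique mappings collapsed into the event and digests the union of
    digest labels seen.  Non-unique statuses are tallied in the QC report.
    """
    groups: dict[tuple[str, int, str], tuple[int, set[str]]] = {}
    qc: Counter[str] = Counter({s.value: 0 for s in MapStatus})
    for m in mappings:
        qc[m.status.value] += 1
        if m.status is MapStatus.UNIQUE:
            key = (m.chrom, m.position, m.strand)
            count, digests = groups.get(key, (0, set()))
            if m.digest:
                digests.add(m.digest)
            groups[key] = (count + 1, digests)
    events = [
        InsertionEvent(chrom, pos, strand, count, frozenset(digests))
        for (chrom, pos, strand), (count, digests) in groups.items()
    ]
    return InsertionSet(
        construct=construct,
        total_aligned_reads=qc[MapStatus.UNIQUE.value],
        events=sorted(events, key=lambda e: (e.chrom, e.position, e.strand)),
        qc=dict(qc),
    )


def import_sam(path: str | Path, genome_names: Iterable[str]) -> Iterator[MappingResult]:
    """Mapping results from externally aligned, already-trimmed reads.

    Primary mapped alignments become UNIQUE calls; the insertion coordinate
    is the alignment start for plus-strand reads and the last aligned
    reference base for minus-strand reads (the junction sits at the 5' end
    of the read in both cases).  Secondary/supplementary records are treated
    as evidence of multi-mapping; unmapped records pass through as UNMAPPED.
    """
    names = set(genome_names)
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                yield MappingResult(rec.query_name, MapStatus.UNMAPPED)
                continue
            if rec.is_secondary or rec.is_supplementary:
                yield MappingResult(rec.query_name, MapStatus.MULTI)
                continue
            chrom = rec.reference_name
            if chrom not in names:
                raise ValueError(
                    f"SAM record {rec.query_name!r} maps to unknown reference {chrom!r}"
                )
            if rec.is_reverse:
                position = rec.reference_end - 1  # last aligned base, 0-based
                strand = "-"
            else:
                position = rec.reference_start
                strand = "+"
            yield MappingResult(rec.query_name, MapStatus.UNIQUE, chrom, position, strand)
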