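"""Genomic feature annotations (origins, Orc1 sites, centromeres, TSSs).

Feature classes mirror the replication-biology site lists the analysis is
built around: ARS consensus sequences (ACSs) split into the oriDB-style
confirmed/likely vs dubious categories, Orc1 ChIP binding sites, centromeres
and transcription start sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .genome import Genome


class FeatureClass(str, Enum):
    ACS_CONFIRMED_LIKELY = "ACS_CONFIRMED_LIKELY"
    ACS_DUBIOUS = "ACS_DUBIOUS"
    ORC1 = "ORC1"
    CENTROMERE = "CENTROMERE"
    TSS = "TSS"


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class FeatureAnnotation:
    """Per-class sorted, non-overlapping site lists on one genome."""

    sites: dict[FeatureClass, list[Interval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls, ivs in self.sites.items():
            ivs.sort(key=lambda iv: (iv.chrom, iv.start))
            by_chrom: dict[str, int] = {}
            for iv in ivs:
                prev_end = by_chrom.get(iv.chrom, -1)
                if iv.start < prev_end:
                    raise ValueError(f"overlapping {cls.value} intervals on {iv.chrom}")
                by_chrom[iv.chrom] = iv.end

    def __getitem__(self, cls: FeatureClass) -> list[Interval]:
        return self.sites.get(cls, [])

    def midpoints(self, cls: FeatureClass) -> list[tuple[str, int]]:
        return [(iv.chrom, iv.midpoint) for iv in self[cls]]

    def validate_against(self, genome: Genome) -> None:
        lengths = genome.lengths
        for cls, ivs in self.sites.items():
            for iv in ivs:
                if iv.chrom not in lengths:
                    raise ValueError(f"{cls.value} interval on unknown chromosome {iv.chrom}")
                if iv.end > lengths[iv.chrom]:
                    raise ValueError(
                        f"{cls.value} interval {iv.chrom}:{iv.start}-{iv.end} "
                        f"exceeds chromosome length {lengths[iv.chrom]}"
                    )

    def to_bed(self, path: str | Path) -> None:
        """6-column BED; the name column carries the feature class."""
        with open(path, "w") as fh:
            for cls in FeatureClass:
                for iv in self.sites.get(cls, []):
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{cls.value}\t0\t+\n")

    @classmethod
    def from_bed(cls, path: str | Path) -> "FeatureAnnotation":
        sites: dict[FeatureClass, list[Interval]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: BED line needs >= 4 columns")
                chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
                try:
                    fc = FeatureClass(name)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: unknown feature class {name!r}") from exc
                sites.setdefault(fc, []).append(Interval(chrom, start, end))
        return cls(sites)
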