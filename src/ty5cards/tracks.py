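"""Normalized genome signal tracks.

Two normalizations of the same insertion set, matching how calling-cards
signal is displayed and summarized:

* RPM — reads per million aligned reads at each position; keeps the
  quantitative (amplification-weighted) signal.
* UNIQUE — a 0/1 indicator of whether any insertion occurred at a
  position; discards read counts and keeps only positional information.

Tracks are unstranded: the two orientations at one position are summed
(RPM) or merged (UNIQUE), matching bedGraph/browser semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from pathlib import Path

import numpy as np

from .reads import InsertionSet


class TrackMode(str, Enum):
    RPM = "RPM"
    UNIQUE = "UNIQUE"


@dataclass
class SignalTrack:
    """Sparse per-position signal: chrom -> (sorted positions, values)."""

    mode: TrackMode
    data: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, val) in self.data.items():
            pos = np.asarray(pos, dtype=int)
            val = np.asarray(val, dtype=float)
            if pos.size != val.size:
                raise ValueError(f"{chrom}: positions/values length mismatch")
            order = np.argsort(pos)
            pos, val = pos[order], val[order]
            if pos.size and np.any(np.diff(pos) == 0):
                raise ValueError(f"{chrom}: duplicate positions in track")
            if np.any(val < 0):
                raise ValueError(f"{chrom}: negative track values")
            if self.mode is TrackMode.UNIQUE and pos.size and not np.all(val == 1.0):
                raise ValueError("UNIQUE track values must all be 1")
            clean[chrom] = (pos, val)
        self.data = clean

    @property
    def n_positions(self) -> int:
        return sum(pos.size for pos, _ in self.data.values())

    def total(self) -> float:
        return float(sum(val.sum() for _, val in self.data.values()))

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self.data.get(chrom, (np.empty(0, dtype=int), np.empty(0)))

    def values_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Values at tracked positions within [start, end)."""
        pos, val = self.chrom_arrays(chrom)
        lo, hi = np.searchsorted(pos, [start, end])
        return val[lo:hi]

    def sum_in(self, chrom: str, start: int, end: int) -> float:
        return float(self.values_in(chrom, start, end).sum())

    def allclose(self, other: "SignalTrack", rtol: float = 1e-9) -> bool:
        if self.mode is not other.mode or set(self.data) != set(other.data):
            return False
        for chrom in self.data:
            p1, v1 = self.data[chrom]
            p2, v2 = other.data[chrom]
            if p1.size != p2.size or not np.array_equal(p1, p2):
                return False
            if not np.allclose(v1, v2, rtol=rtol, atol=0):
                return False
        return True


def _collapse_strands(events) -> dict[str, dict[int, int]]:
    per_chrom: dict[str, dict[int, int]] = {}
    for e in events:
        per_chrom.setdefault(e.chrom, {})
        per_chrom[e.chrom][e.position] = per_chrom[e.chrom].get(e.position, 0) + e.read_count
    return per_chrom


def rpm_track(insertions: InsertionSet) -> SignalTrack:
    """Reads-per-million track: value(p) = 1e6 * reads(p) / aligned reads.

    Values are computed as reduced rationals before the float conversion so
    that uniformly duplicating every read leaves the track bit-identical.
    """
    if insertions.total_aligned_reads <= 0:
        raise ValueError("total_aligned_reads must be positive for RPM normalization")
    total = insertions.total_aligned_reads
    data = {}
    for chrom, counts in _collapse_strands(insertions.events).items():
        pos = np.array(sorted(counts), dtype=int)
        val = np.array([float(Fraction(counts[p] * 10**6, total)) for p in pos])
        data[chrom] = (pos, val)
    return SignalTrack(TrackMode.RPM, data)


def unique_track(insertions: InsertionSet) -> SignalTrack:
    """Unique-insertion indicator track: 1 wherever any insertion occurred."""
    data = {}
    for chrom, counts in _collapse_strands(insertions.events).items():
        pos = np.array(sorted(counts), dtype=int)
        data[chrom] = (pos, np.ones(pos.size))
    return SignalTrack(TrackMode.UNIQUE, data)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Single-base 0-based half-open bedGraph with the mode in a header."""
    with open(path, "w") as fh:
        fh.write(f"#mode={track.mode.value}\n")
        for chrom in sorted(track.data):
            pos, val = track.data[chrom]
            for p, v in zip(pos, val):
                fh.write(f"{chrom}\t{p}\t{p + 1}\t{float(v)!r}\n")


def read_bedgraph(path: str | Path) -> SignalTrack:
    mode = TrackMode.RPM
    data: dict[str, tuple[list[int], list[float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("#mode="):
                mode = TrackMode(line.split("=", 1)[1])
                continue
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: bedGraph line needs 4 columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            pos, val = data.setdefault(chrom, ([], []))
            for p in range(start, end):
                pos.append(p)
                val.append(value)
    return SignalTrack(
        mode,
        {c: (np.array(p, dtype=int), np.array(v)) for c, (p, v) in data.items()},
    )
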