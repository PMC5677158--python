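"""Replication-timing (T_rep) profiles.

T_rep is the time in S phase, in minutes, at which half the cells in a
population have replicated a locus.  A profile assigns a T_rep value to
every genomic position; internally it is a dense per-chromosome float array,
serialized to bedGraph with equal-value runs merged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome import Genome


@dataclass
class TimingProfile:
    """Per-chromosome T_rep landscape covering every position exactly once."""

    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1 or arr.size == 0:
                raise ValueError(f"timing for {chrom} must be a non-empty 1-D array")
            if np.any(arr < 0):
                raise ValueError(f"negative T_rep on {chrom}")
            self.values[chrom] = arr

    def value_at(self, chrom: str, pos: int) -> float:
        arr = self.values.get(chrom)
        if arr is None:
            raise KeyError(f"no timing data for chromosome {chrom!r}")
        if not 0 <= pos < arr.size:
            raise IndexError(f"position {pos} outside timing coverage of {chrom}")
        return float(arr[pos])

    def lookup(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        arr = self.values.get(chrom)
        if arr is None:
            raise KeyError(f"no timing data for chromosome {chrom!r}")
        positions = np.asarray(positions, dtype=int)
        if positions.size and (positions.min() < 0 or positions.max() >= arr.size):
            raise IndexError(f"positions outside timing coverage of {chrom}")
        return arr[positions]

    @property
    def t_max(self) -> float:
        return max(float(arr.max()) for arr in self.values.values())

    def genome_mean(self) -> float:
        total = sum(float(arr.sum()) for arr in self.values.values())
        n = sum(arr.size for arr in self.values.values())
        return total / n

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tstart\tend\tTrep_min\n")
            for chrom in sorted(self.values):
                arr = self.values[chrom]
                # merge runs of identical value
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [arr.size]))
                for s, e in zip(starts, ends):
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:.6g}\n")

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "TimingProfile":
        spans: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: bedGraph line needs 4 columns")
                chrom, start, end, val = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                spans.setdefault(chrom, []).append((start, end, val))
        values: dict[str, np.ndarray] = {}
        for chrom, runs in spans.items():
            runs.sort()
            size = runs[-1][1]
            arr = np.full(size, np.nan)
            for s, e, v in runs:
                arr[s:e] = v
            if np.isnan(arr).any():
                raise ValueError(f"timing profile for {chrom} does not cover every position")
            values[chrom] = arr
        return cls(values)


def synth_timing(
    genome: Genome,
    origins: dict[str, list[int]],
    fork_rate: float,
    t0: float,
    t_max: float = 70.0,
) -> TimingProfile:
    """Distance-to-nearest-origin timing landscape.

    T_rep(p) = t0 + min_o |p - o| / fork_rate, capped at ``t_max``: forks
    move outward from each origin at a constant rate, so timing grows
    linearly with distance from the nearest origin and is minimal (= t0)
    exactly at origins.
    """
    if fork_rate <= 0:
        raise ValueError("fork_rate must be positive")
    values: dict[str, np.ndarray] = {}
    for name, seq in genome.chromosomes:
        oris = sorted(origins.get(name, []))
        if not oris:
            raise ValueError(f"chromosome {name} has no origin")
        if oris[0] < 0 or oris[-1] >= len(seq):
            raise ValueError(f"origin outside chromosome {name}")
        pos = np.arange(len(seq))
        dist = np.min(np.abs(pos[:, None] - np.array(oris)[None, :]), axis=1)
        values[name] = np.minimum(t0 + dist / fork_rate, t_max)
    return TimingProfile(values)
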