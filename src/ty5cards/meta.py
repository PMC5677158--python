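"""Replication-timing window statistics and feature-centered meta-profiles.

Two summaries of a signal track drive the biology here:

* timing windows — the genome is partitioned into 5-minute T_rep windows
  and the mean per-position signal (zeros included) computed per window;
  binding coupled to early replication shows up as a decreasing staircase.
* meta-profiles — fixed-width bins tiled around feature midpoints (ACSs,
  Orc1 sites, centromeres, TSSs), averaging the per-position signal per bin
  over all sites; origin-proximal binding appears as a central peak.

Both use the mean per genomic position *including untracked (zero)
positions*, so RPM and unique-insertion tracks are summarized on the same
density scale and windows of different extent are comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import Interval
from .reads import InsertionSet
from .timing import TimingProfile
from .tracks import SignalTrack


@dataclass
class WindowSummary:
    """Signal of one construct in one [t_lo, t_hi) replication-timing window.

    ``n_positions`` counts every genomic position whose T_rep falls in the
    window; ``tracked_values`` holds the signal at the (typically sparse)
    tracked positions among them.  ``mean`` is total signal per genomic
    position, i.e. zeros at untracked positions are part of the average.
    The last window of a partition is open-ended on the right.
    """

    construct: str
    t_lo: float
    t_hi: float
    n_positions: int
    tracked_values: np.ndarray
    open_right: bool = False

    @property
    def n_tracked(self) -> int:
        return int(self.tracked_values.size)

    @property
    def total(self) -> float:
        return float(self.tracked_values.sum())

    @property
    def mean(self) -> float:
        return self.total / self.n_positions if self.n_positions else math.nan

    def values(self) -> np.ndarray:
        """Per-position signal over every genomic position in the window."""
        full = np.zeros(self.n_positions)
        full[: self.tracked_values.size] = self.tracked_values
        return full


def filter_by_timing(
    insertions: InsertionSet, timing: TimingProfile, t_max: float = 30.0
) -> InsertionSet:
    """Keep events in DNA replicating by ``t_max`` minutes.

    The library denominator (total aligned reads) is deliberately left
    unchanged: RPM normalization refers to the whole library, not the
    early-replicating subset.
    """
    kept = []
    for e in insertions.events:
        try:
            trep = timing.value_at(e.chrom, e.position)
        except (KeyError, IndexError) as exc:
            raise ValueError(f"event at {e.chrom}:{e.position} outside timing coverage") from exc
        if trep <= t_max:
            kept.append(e)
    return InsertionSet(
        construct=insertions.construct,
        total_aligned_reads=insertions.total_aligned_reads,
        events=kept,
        qc=dict(insertions.qc),
    )


def timing_window_signal(
    track: SignalTrack,
    timing: TimingProfile,
    width: float = 5.0,
    t_max: float | None = None,
    construct: str = "",
) -> list[WindowSummary]:
    """Partition the genome into T_rep windows and summarize track signal.

    Windows are left-closed ([0, w), [w, 2w), ...) and the last window is
    open-ended so every position lands in exactly one window.  Positions
    are assigned by the timing profile; tracked positions carry their
    signal, all others contribute zeros to the window mean.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    if t_max is None:
        t_max = timing.t_max
    n_win = max(1, math.ceil(t_max / width - 1e-12))
    counts = np.zeros(n_win, dtype=int)
    tracked: list[list[np.ndarray]] = [[] for _ in range(n_win)]
    for chrom, arr in timing.values.items():
        widx = np.minimum((arr / width).astype(int), n_win - 1)
        counts += np.bincount(widx, minlength=n_win)
        pos, val = track.chrom_arrays(chrom)
        if pos.size:
            pw = np.minimum((timing.lookup(chrom, pos) / width).astype(int), n_win - 1)
            for w in np.unique(pw):
                tracked[w].append(val[pw == w])
    out = []
    for w in range(n_win):
        vals = np.concatenate(tracked[w]) if tracked[w] else np.empty(0)
        out.append(
            WindowSummary(
                construct=construct,
                t_lo=w * width,
                t_hi=(w + 1) * width,
                n_positions=int(counts[w]),
                tracked_values=vals,
                open_right=(w == n_win - 1),
            )
        )
    return out


def windows_to_tsv(windows: list[WindowSummary], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("construct\tt_lo\tt_hi\tn_positions\tn_tracked\tmean\n")
        for w in windows:
            hi = "inf" if w.open_right else f"{w.t_hi:g}"
            fh.write(
                f"{w.construct}\t{w.t_lo:g}\t{hi}\t{w.n_positions}\t{w.n_tracked}\t{w.mean!r}\n"
            )


@dataclass
class MetaProfile:
    """Mean per-position signal in fixed bins around feature midpoints.

    ``offsets`` are bin left edges relative to the midpoint; bins tile
    [-flank, +flank) exactly.  ``values[b]`` is the mean over sites of
    (bin signal mass / bin_width).  Sites whose full window would run off a
    chromosome end are dropped and counted in ``n_dropped``.
    """

    feature_class: str
    flank: int
    bin_width: int
    offsets: np.ndarray
    values: np.ndarray
    n_sites: int
    n_dropped: int = 0

    @property
    def n_bins(self) -> int:
        return int(self.offsets.size)

    @property
    def centers(self) -> np.ndarray:
        return self.offsets + self.bin_width / 2

    def argmax_offset(self) -> float:
        """Center offset of the highest bin."""
        return float(self.centers[int(np.argmax(self.values))])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#feature_class={self.feature_class}\n")
            fh.write(
                f"#flank={self.flank}\t#bin_width={self.bin_width}"
                f"\t#n_sites={self.n_sites}\t#n_dropped={self.n_dropped}\n"
            )
            fh.write("offset_lo\toffset_hi\tmean\n")
            for off, v in zip(self.offsets, self.values):
                fh.write(f"{int(off)}\t{int(off) + self.bin_width}\t{float(v)!r}\n")


def feature_profile(
    track: SignalTrack,
    sites: list[Interval],
    chrom_sizes: dict[str, int],
    flank: int,
    bin_width: int,
    feature_class: str = "",
) -> MetaProfile:
    """Meta-profile of track signal around feature midpoints.

    For each site, the window [midpoint - flank, midpoint + flank) is tiled
    into bins of ``bin_width``; each bin's value is its signal mass divided
    by ``bin_width`` (mean per position, zeros included), and the profile
    averages bins across sites.
    """
    if not sites:
        raise ValueError("no feature sites supplied")
    if flank % bin_width != 0:
        raise ValueError("flank must be divisible by bin_width")
    n_bins = 2 * flank // bin_width
    offsets = np.arange(-flank, flank, bin_width)
    sums = np.zeros(n_bins)
    n_used = 0
    n_dropped = 0
    # per-chromosome prefix sums over tracked values for O(log n) bin masses
    cumul: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {s.chrom for s in sites}:
        pos, val = track.chrom_arrays(chrom)
        cumul[chrom] = (pos, np.concatenate(([0.0], np.cumsum(val))))
    for site in sites:
        size = chrom_sizes.get(site.chrom)
        if size is None:
            raise ValueError(f"site on unknown chromosome {site.chrom!r}")
        mid = site.midpoint
        if mid - flank < 0 or mid + flank > size:
            n_dropped += 1
            continue
        pos, csum = cumul[site.chrom]
        edges = np.searchsorted(pos, mid + np.arange(-flank, flank + 1, bin_width))
        sums += csum[edges[1:]] - csum[edges[:-1]]
        n_used += 1
    if n_used == 0:
        raise ValueError("no sites remain after chromosome-end truncation")
    return MetaProfile(
        feature_class=feature_class,
        flank=flank,
        bin_width=bin_width,
        offsets=offsets,
        values=sums / (n_used * bin_width),
        n_sites=n_used,
        n_dropped=n_dropped,
    )


def profile_ratio(
    a: MetaProfile, b: MetaProfile, region: tuple[int, int] = (-100, 100)
) -> float:
    """Fold ratio of mean bin values a/b over a central offset range.

    Bins fully inside [region[0], region[1]) are averaged in each profile.
    Returns NaN (a flagged undefined ratio) when both central means are 0.
    """
    if (
        a.flank != b.flank
        or a.bin_width != b.bin_width
        or not np.array_equal(a.offsets, b.offsets)
    ):
        raise ValueError("profiles must share binning to be compared")
    lo, hi = region
    mask = (a.offsets >= lo) & (a.offsets + a.bin_width <= hi)
    if not mask.any():
        raise ValueError("offset region contains no complete bin")
    num = float(a.values[mask].mean())
    den = float(b.values[mask].mean())
    if num == 0.0 and den == 0.0:
        return math.nan
    if den == 0.0:
        return math.inf
    return num / den
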