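"""Synthetic calling-cards data generator.

Builds everything the analysis consumes without any external download: a toy
genome, feature annotations, a replication-timing landscape, ground-truth
Ty5 insertion events, and FASTQ junction-read libraries produced by a
three-enzyme digest / circularization / inverse-PCR model with per-insertion
amplification bias.

The insertion placement model is multiplicative: a uniform background rate,
an exponential enrichment kernel around feature midpoints (fold ``e``
decaying over ``lam`` bp), and an exponential coupling to replication
timing (weight exp(-T_rep / tau)), so early-replicating DNA receives more
insertions when ``tau`` is finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FeatureAnnotation, FeatureClass, Interval
from .genome import Genome, revcomp
from .timing import TimingProfile, synth_timing

DEFAULT_ENZYMES = {"HindIII": "AAGCTT", "HpaII": "CCGG", "TaqI": "TCGA"}
# fixed synthetic Ty5 terminal tag: the transposon-side prefix of every
# junction read, trimmed off before mapping (configurable, 20 bp)
DEFAULT_TAG = "TGTTGGAATAGCAAGGCAGT"
ACS_WIDTH = 11  # the ARS consensus sequence is an 11 bp motif


@dataclass(frozen=True)
class Enrichment:
    """Fold enrichment ``e`` >= 1 decaying exponentially over ``lam`` bp."""

    fold: float
    lam: float

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("enrichment fold must be >= 1")
        if self.lam <= 0:
            raise ValueError("decay length must be positive")


@dataclass(frozen=True)
class SimParams:
    """Parameters of the insertion-placement and read models.

    ``timing_tau`` is in minutes; ``math.inf`` disables timing coupling.
    ``pcr_mu``/``pcr_sigma`` parameterize the log-normal per-insertion
    amplification factor.  ``enzymes`` maps digest label to recognition
    sequence.
    """

    n_insertions: int = 1000
    background_rate: float = 1.0
    feature_enrichment: dict[FeatureClass, Enrichment] = field(default_factory=dict)
    timing_tau: float = math.inf
    pcr_mu: float = 0.5
    pcr_sigma: float = 0.8
    read_length: int = 50
    tag: str = DEFAULT_TAG
    enzymes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ENZYMES))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_insertions < 0:
            raise ValueError("n_insertions must be >= 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.timing_tau <= 0:
            raise ValueError("timing_tau must be positive (inf to disable)")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if not self.enzymes:
            raise ValueError("at least one restriction enzyme is required")
        if len(self.tag) < 8:
            raise ValueError("tag must be >= 8 bp")


@dataclass(frozen=True)
class TrueInsertion:
    chrom: str
    position: int  # 0-based first genomic base 3' of the junction, plus strand
    strand: str
    n_fragments: int
    n_reads: int


@dataclass
class SimTruth:
    """Ground-truth insertion table plus the parameters that produced it."""

    insertions: list[TrueInsertion]
    params: SimParams

    def __post_init__(self) -> None:
        keys = {(i.chrom, i.position, i.strand) for i in self.insertions}
        if len(keys) != len(self.insertions):
            raise ValueError("duplicate (chrom, position, strand) in truth table")
        for ins in self.insertions:
            if not ins.n_reads >= ins.n_fragments >= 1:
                raise ValueError("truth requires n_reads >= n_fragments >= 1")

    def positions(self) -> set[tuple[str, int, str]]:
        return {(i.chrom, i.position, i.strand) for i in self.insertions}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tposition\tstrand\tn_fragments\tn_reads\n")
            for i in sorted(self.insertions, key=lambda x: (x.chrom, x.position, x.strand)):
                fh.write(f"{i.chrom}\t{i.position}\t{i.strand}\t{i.n_fragments}\t{i.n_reads}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, params: SimParams | None = None) -> "SimTruth":
        rows = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("chrom"):
                raise ValueError(f"{path}: missing truth header")
            for line in fh:
                c, p, s, nf, nr = line.rstrip("\n").split("\t")
                rows.append(TrueInsertion(c, int(p), s, int(nf), int(nr)))
        return cls(rows, params or SimParams(n_insertions=len(rows)))


def generate_genome(
    n_chrom: int, lengths: list[int], gc: float, seed: int
) -> Genome:
    """Random genome with independent bases at the requested GC fraction."""
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if len(lengths) != n_chrom:
        raise ValueError("lengths must have one entry per chromosome")
    if any(length < 1000 for length in lengths):
        raise ValueError("chromosome lengths must be >= 1000")
    if not 0 < gc < 1:
        raise ValueError("gc must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype="S1")
    chroms = []
    for i, length in enumerate(lengths):
        draw = rng.choice(bases, size=length, p=probs)
        chroms.append((f"chr{i + 1}", draw.tobytes().decode("ascii")))
    return Genome(tuple(chroms))


def annotate_features(
    genome: Genome,
    counts: dict[FeatureClass, int],
    spacing_min: int,
    seed: int,
    widths: dict[FeatureClass, int] | None = None,
) -> FeatureAnnotation:
    """Place non-overlapping feature intervals at random, spaced >= spacing_min.

    ACS classes default to the 11 bp consensus width; other classes to a
    single-base site (their analyses use midpoints only).  Sites of each
    class are spread across chromosomes proportionally to length.
    """
    default_widths = {
        FeatureClass.ACS_CONFIRMED_LIKELY: ACS_WIDTH,
        FeatureClass.ACS_DUBIOUS: ACS_WIDTH,
        FeatureClass.ORC1: 1,
        FeatureClass.CENTROMERE: 1,
        FeatureClass.TSS: 1,
    }
    if widths:
        default_widths.update(widths)
    rng = np.random.default_rng(seed)
    sites: dict[FeatureClass, list[Interval]] = {}
    lengths = genome.lengths
    total = genome.total_length
    for cls, count in counts.items():
        if count == 0:
            sites[cls] = []
            continue
        width = default_widths[cls]
        pitch = spacing_min + width
        capacity = sum(max(0, (length - width) // pitch + 1) for length in lengths.values())
        if count > capacity:
            raise ValueError(
                f"cannot place {count} {cls.value} sites with spacing {spacing_min}: "
                f"capacity is {capacity}"
            )
        # apportion per chromosome by length, then place on an even lattice
        # with random jitter that preserves the minimum gap
        remaining = count
        ivs: list[Interval] = []
        names = genome.names
        for j, name in enumerate(names):
            length = lengths[name]
            if j == len(names) - 1:
                want = remaining
            else:
                want = min(remaining, round(count * length / total))
            cap = max(0, (length - width) // pitch + 1)
            want = min(want, cap)
            if want == 0:
                continue
            stride = max(length // want, pitch)
            jitter_max = max(0, stride - pitch)
            for k in range(want):
                start = k * stride
                if jitter_max:
                    start += int(rng.integers(0, jitter_max + 1))
                ivs.append(Interval(name, start, start + width))
            remaining -= want
        if remaining > 0:
            raise ValueError(
                f"cannot place {count} {cls.value} sites with spacing {spacing_min}"
            )
        sites[cls] = ivs
    ann = FeatureAnnotation(sites)
    ann.validate_against(genome)
    return ann


def synth_timing_from_annotation(
    genome: Genome,
    annotation: FeatureAnnotation,
    origin_stride: int,
    fork_rate: float,
    t0: float,
    t_max: float = 70.0,
) -> TimingProfile:
    """Timing landscape anchored at a subset of confirmed/likely ACS sites.

    Every ``origin_stride``-th confirmed/likely ACS per chromosome fires as
    a replication origin (at least one per chromosome), mimicking that only
    a fraction of licensed origins fire early.
    """
    if origin_stride < 1:
        raise ValueError("origin_stride must be >= 1")
    origins: dict[str, list[int]] = {name: [] for name in genome.names}
    for chrom, mid in annotation.midpoints(FeatureClass.ACS_CONFIRMED_LIKELY):
        origins.setdefault(chrom, []).append(mid)
    picked = {}
    for chrom, mids in origins.items():
        mids.sort()
        picked[chrom] = mids[::origin_stride] if mids else []
    return synth_timing(genome, picked, fork_rate, t0, t_max)


def _nearest_midpoint_distance(length: int, midpoints: list[int]) -> np.ndarray:
    """Per-position distance to the nearest midpoint (inf if none)."""
    if not midpoints:
        return np.full(length, np.inf)
    mids = np.sort(np.asarray(midpoints))
    pos = np.arange(length)
    idx = np.searchsorted(mids, pos)
    left = np.where(idx > 0, np.abs(pos - mids[np.maximum(idx - 1, 0)]), np.inf)
    right = np.where(idx < mids.size, np.abs(mids[np.minimum(idx, mids.size - 1)] - pos), np.inf)
    return np.minimum(left, right)


def insertion_weights(
    genome: Genome,
    annotation: FeatureAnnotation,
    timing: TimingProfile | None,
    params: SimParams,
) -> dict[str, np.ndarray]:
    """Per-base sampling weight w(p) for every chromosome.

    w(p) = background * prod_c [1 + (e_c - 1) exp(-d_c(p)/lam_c)]
                      * exp(-T_rep(p)/tau)
    where d_c(p) is the distance to the nearest class-c feature midpoint.
    """
    weights: dict[str, np.ndarray] = {}
    for name, seq in genome.chromosomes:
        w = np.full(len(seq), params.background_rate, dtype=float)
        for cls, enr in params.feature_enrichment.items():
            mids = [m for c, m in annotation.midpoints(cls) if c == name]
            d = _nearest_midpoint_distance(len(seq), mids)
            with np.errstate(over="ignore"):
                w *= 1.0 + (enr.fold - 1.0) * np.exp(-d / enr.lam)
        if math.isfinite(params.timing_tau):
            if timing is None:
                raise ValueError("timing_tau is finite but no timing profile given")
            w *= np.exp(-timing.values[name] / params.timing_tau)
        weights[name] = w
    return weights


def sample_insertions(
    genome: Genome,
    annotation: FeatureAnnotation,
    timing: TimingProfile | None,
    params: SimParams,
) -> SimTruth:
    """Draw ground-truth insertions proportional to the per-base weights.

    Positions are sampled without replacement (Gumbel top-k over log
    weights), strands are fair coin flips, and each insertion receives a
    log-normal PCR amplification factor that multiplies its per-digest read
    count.  Deterministic for a fixed ``params.seed``.
    """
    if params.n_insertions > genome.total_length:
        raise ValueError("n_insertions exceeds genome length")
    rng = np.random.default_rng(params.seed)
    if params.n_insertions == 0:
        return SimTruth([], params)
    weights = insertion_weights(genome, annotation, timing, params)
    chrom_names = genome.names
    flat = np.concatenate([weights[name] for name in chrom_names])
    offsets = np.cumsum([0] + [len(weights[name]) for name in chrom_names])
    with np.errstate(divide="ignore"):
        logw = np.log(flat)
    keys = logw + rng.gumbel(size=flat.size)
    top = np.argpartition(-keys, params.n_insertions - 1)[: params.n_insertions]
    top.sort()
    strands = rng.random(params.n_insertions) < 0.5
    amp = np.maximum(1, np.rint(rng.lognormal(params.pcr_mu, params.pcr_sigma, params.n_insertions))).astype(int)
    n_frag = len(params.enzymes)
    insertions = []
    for flat_pos, minus, a in zip(top, strands, amp):
        ci = int(np.searchsorted(offsets, flat_pos, side="right")) - 1
        insertions.append(
            TrueInsertion(
                chrom=chrom_names[ci],
                position=int(flat_pos - offsets[ci]),
                strand="-" if minus else "+",
                n_fragments=n_frag,
                n_reads=n_frag * int(a),
            )
        )
    return SimTruth(insertions, params)


@dataclass(frozen=True)
class SimRead:
    """One synthetic junction read (FASTQ semantics, constant quality)."""

    id: str
    sequence: str

    @property
    def quality(self) -> str:
        return "I" * len(self.sequence)


@dataclass
class LibraryStats:
    reads_emitted: int = 0
    fragments_dropped: int = 0  # digest escape: no recognition site downstream
    fragments_short: int = 0  # cut site closer than one base
    reads_lost: int = 0


def _junction_fragment(
    seq: str, position: int, strand: str, site: str
) -> str | None:
    """Genomic fragment from the insertion point to the nearest downstream
    recognition site on the insertion strand; None if the digest escapes."""
    if strand == "+":
        cut = seq.find(site, position + 1)
        if cut == -1:
            return None
        return seq[position:cut]
    # minus strand: downstream is leftward on the plus strand; the fragment
    # is read off the minus strand starting at the junction base.  rfind with
    # end=position only admits occurrences that end at or before the junction.
    cut = seq.rfind(site, 0, position)
    if cut == -1:
        return None
    return revcomp(seq[cut + len(site) : position + 1])


def simulate_library(
    genome: Genome, truth: SimTruth, params: SimParams | None = None
) -> tuple[list[SimRead], LibraryStats]:
    """Emit junction reads for every truth insertion and every digest.

    Each insertion's ``n_reads`` total is split evenly across the digests
    (the three inverse-PCR reactions are pooled into one library).  A digest
    whose recognition site never occurs downstream of the junction drops its
    fragment, and that digest's share of reads is counted as lost.
    Reads are ``tag + fragment`` truncated to ``read_length``.
    """
    params = params or truth.params
    seqs = dict(genome.chromosomes)
    tag = params.tag
    frag_len = params.read_length - len(tag)
    if frag_len < 1:
        raise ValueError("read_length must exceed tag length")
    enzymes = list(params.enzymes.items())
    reads: list[SimRead] = []
    stats = LibraryStats()
    for idx, ins in enumerate(sorted(truth.insertions, key=lambda x: (x.chrom, x.position, x.strand))):
        seq = seqs.get(ins.chrom)
        if seq is None or ins.position >= len(seq):
            raise ValueError(f"truth insertion outside genome: {ins.chrom}:{ins.position}")
        base, rem = divmod(ins.n_reads, len(enzymes))
        for ei, (label, site) in enumerate(enzymes):
            share = base + (1 if ei < rem else 0)
            if share == 0:
                continue
            frag = _junction_fragment(seq, ins.position, ins.strand, site)
            if frag is None:
                stats.fragments_dropped += 1
                stats.reads_lost += share
                continue
            if not frag:
                stats.fragments_short += 1
                stats.reads_lost += share
                continue
            read_seq = (tag + frag)[: params.read_length]
            for rep in range(share):
                reads.append(
                    SimRead(
                        id=f"ins{idx:06d}|{label}|rep{rep}",
                        sequence=read_seq,
                    )
                )
                stats.reads_emitted += 1
    return reads, stats


def write_fastq(reads: list[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")
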