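"""End-to-end orchestration: simulate a calling-cards experiment to disk,
and analyze a read library into tracks, window statistics and meta-profiles.

The default simulation scenario is a desk-scale stand-in for the real
experiment: a quarter-megabase two-chromosome genome at yeast-like GC,
origin-anchored replication timing, and a construct that integrates Ty5
preferentially near confirmed/likely ACS sites and in early-replicating
DNA, with log-normal inverse-PCR amplification bias.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

from .features import FeatureAnnotation, FeatureClass
from .genome import Genome, GenomeIndex
from .meta import feature_profile, filter_by_timing, timing_window_signal, windows_to_tsv
from .reads import InsertionSet, call_insertions, import_sam, map_reads, read_fastq
from .simulate import (
    DEFAULT_TAG,
    Enrichment,
    SimParams,
    annotate_features,
    generate_genome,
    sample_insertions,
    simulate_library,
    synth_timing_from_annotation,
    write_fastq,
)
from .timing import TimingProfile
from .tracks import rpm_track, unique_track, write_bedgraph

__version__ = "0.1.0"

# feature-class profile geometry: (flank bp, bin width bp)
PROFILE_GEOMETRY: dict[FeatureClass, tuple[int, int]] = {
    FeatureClass.ACS_CONFIRMED_LIKELY: (1000, 100),
    FeatureClass.ACS_DUBIOUS: (1000, 100),
    FeatureClass.ORC1: (5000, 100),
    FeatureClass.CENTROMERE: (5000, 100),
    FeatureClass.TSS: (1000, 100),
}


@dataclass
class SimulateConfig:
    """Parameters of the default synthetic experiment."""

    chrom_lengths: list[int] = field(default_factory=lambda: [150_000, 100_000])
    gc: float = 0.38
    counts: dict[str, int] = field(
        default_factory=lambda: {
            "ACS_CONFIRMED_LIKELY": 24,
            "ACS_DUBIOUS": 12,
            "ORC1": 24,
            "CENTROMERE": 2,
            "TSS": 40,
        }
    )
    spacing_min: int = 2000
    origin_stride: int = 3  # every k-th confirmed/likely ACS fires as a timing origin
    fork_rate: float = 500.0  # bp/min
    t0: float = 5.0  # minutes; earliest-firing origins
    t_max: float = 70.0
    n_insertions: int = 5000
    acs_fold: float = 50.0
    acs_lambda: float = 100.0
    timing_tau: float = 15.0  # minutes; inf disables early-replication bias
    pcr_mu: float = 0.5
    pcr_sigma: float = 0.8
    read_length: int = 50
    tag: str = DEFAULT_TAG
    construct: str = "cdc7KD-sir4"
    seed: int = 0


@dataclass
class AnalyzeConfig:
    """Paths and parameters of one construct's analysis run."""

    genome_fasta: str
    reads_fastq: str | None = None
    reads_sam: str | None = None
    features_bed: str | None = None
    timing_bedgraph: str | None = None
    construct: str = "construct"
    tag: str = DEFAULT_TAG
    max_mismatch: int = 0
    min_frag: int = 18
    t_filter: float = 30.0  # minutes; early-replication subset for profiles
    window_width: float = 5.0


def config_hash(cfg) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def sim_params(cfg: SimulateConfig) -> SimParams:
    enrichment = {}
    if cfg.acs_fold > 1:
        enrichment[FeatureClass.ACS_CONFIRMED_LIKELY] = Enrichment(cfg.acs_fold, cfg.acs_lambda)
    return SimParams(
        n_insertions=cfg.n_insertions,
        feature_enrichment=enrichment,
        timing_tau=cfg.timing_tau,
        pcr_mu=cfg.pcr_mu,
        pcr_sigma=cfg.pcr_sigma,
        read_length=cfg.read_length,
        tag=cfg.tag,
        seed=cfg.seed,
    )


def build_scenario(cfg: SimulateConfig):
    """Genome, annotation and timing profile of the synthetic experiment."""
    genome = generate_genome(len(cfg.chrom_lengths), cfg.chrom_lengths, cfg.gc, cfg.seed)
    counts = {FeatureClass(k): v for k, v in cfg.counts.items()}
    annotation = annotate_features(genome, counts, cfg.spacing_min, cfg.seed + 1)
    timing = synth_timing_from_annotation(
        genome, annotation, cfg.origin_stride, cfg.fork_rate, cfg.t0, cfg.t_max
    )
    return genome, annotation, timing


def simulate_and_call(cfg: SimulateConfig, scenario=None):
    """In-memory end-to-end run: simulate a library and call it back.

    Returns (genome, annotation, timing, truth, insertions).  ``scenario``
    may supply a pre-built (genome, annotation, timing) triple so several
    construct libraries share one genome.
    """
    genome, annotation, timing = scenario if scenario is not None else build_scenario(cfg)
    params = sim_params(cfg)
    truth = sample_insertions(genome, annotation, timing, params)
    reads, _ = simulate_library(genome, truth, params)
    index = GenomeIndex(genome)
    insertions = call_insertions(map_reads(reads, index, params.tag), cfg.construct)
    return genome, annotation, timing, truth, insertions


def run_simulate(cfg: SimulateConfig, out_dir: str | Path) -> dict:
    """Write the full synthetic bundle: FASTA, FASTQ, truth TSV, BED, bedGraph."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    genome, annotation, timing = build_scenario(cfg)
    params = sim_params(cfg)
    truth = sample_insertions(genome, annotation, timing, params)
    reads, stats = simulate_library(genome, truth, params)

    paths = {
        "genome_fasta": out / "genome.fasta",
        "reads_fastq": out / f"{cfg.construct}.fastq",
        "truth_tsv": out / "truth.tsv",
        "features_bed": out / "features.bed",
        "timing_bedgraph": out / "timing.bedgraph",
    }
    genome.to_fasta(paths["genome_fasta"])
    write_fastq(reads, paths["reads_fastq"])
    truth.to_tsv(paths["truth_tsv"])
    annotation.to_bed(paths["features_bed"])
    timing.to_bedgraph(paths["timing_bedgraph"])

    manifest = {
        "version": __version__,
        "config_hash": config_hash(cfg),
        "construct": cfg.construct,
        "outputs": {k: str(v) for k, v in paths.items()},
        "n_insertions": len(truth.insertions),
        "reads_emitted": stats.reads_emitted,
        "reads_lost_digest_escape": stats.reads_lost,
        "fragments_dropped": stats.fragments_dropped,
        "wall_clock_s": round(time.time() - t_start, 3),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def run_analyze(cfg: AnalyzeConfig, out_dir: str | Path) -> dict:
    """Full analysis of one construct library.

    Stages: call insertions -> RPM + unique tracks -> timing-window signal
    (if timing given) -> early-replication filter -> per-feature-class
    meta-profiles (if features given).  Every intermediate is written so
    stages can be re-run individually from disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    genome = Genome.from_fasta(cfg.genome_fasta)
    if cfg.reads_fastq:
        index = GenomeIndex(genome)
        mappings = map_reads(
            read_fastq(cfg.reads_fastq), index, cfg.tag, cfg.max_mismatch, cfg.min_frag
        )
    elif cfg.reads_sam:
        mappings = import_sam(cfg.reads_sam, genome.names)
    else:
        raise ValueError("either reads_fastq or reads_sam is required")
    insertions = call_insertions(mappings, cfg.construct)
    insertions.to_tsv(out / "insertions.tsv")
    insertions.qc_json(out / "qc.json")

    report: dict = {
        "version": __version__,
        "config_hash": config_hash(cfg),
        "construct": cfg.construct,
        "n_events": len(insertions),
        "total_aligned_reads": insertions.total_aligned_reads,
        "qc": dict(insertions.qc),
        "warnings": [],
    }
    if len(insertions) == 0:
        report["warnings"].append("no insertion events called; downstream stages skipped")
        _finish(report, out, t_start)
        return report

    rpm = rpm_track(insertions)
    uniq = unique_track(insertions)
    write_bedgraph(rpm, out / "rpm.bedgraph")
    write_bedgraph(uniq, out / "unique.bedgraph")

    timing = None
    if cfg.timing_bedgraph:
        timing = TimingProfile.from_bedgraph(cfg.timing_bedgraph)
        for mode, track in (("rpm", rpm), ("unique", uniq)):
            windows = timing_window_signal(track, timing, cfg.window_width, construct=cfg.construct)
            windows_to_tsv(windows, out / f"windows_{mode}.tsv")
        report["n_windows"] = math.ceil(timing.t_max / cfg.window_width)
    else:
        report["warnings"].append("no timing profile; window signal and 30-min filter skipped")

    if cfg.features_bed:
        annotation = FeatureAnnotation.from_bed(cfg.features_bed)
        if timing is not None:
            early = filter_by_timing(insertions, timing, cfg.t_filter)
            report["n_events_early"] = len(early)
        else:
            early = insertions
        if len(early) == 0:
            report["warnings"].append("no early-replicating events; profiles skipped")
        else:
            profile_tracks = {"rpm": rpm_track(early), "unique": unique_track(early)}
            sizes = genome.lengths
            for fc, (flank, bin_width) in PROFILE_GEOMETRY.items():
                sites = annotation[fc]
                if not sites:
                    continue
                for mode, track in profile_tracks.items():
                    prof = feature_profile(track, sites, sizes, flank, bin_width, fc.value)
                    prof.to_tsv(out / f"profile_{fc.value}_{mode}.tsv")
                    report.setdefault("profiles", {})[f"{fc.value}_{mode}"] = {
                        "n_sites": prof.n_sites,
                        "n_dropped": prof.n_dropped,
                        "argmax_offset": prof.argmax_offset(),
                    }
    _finish(report, out, t_start)
    return report


def _finish(report: dict, out: Path, t_start: float) -> None:
    report["wall_clock_s"] = round(time.time() - t_start, 3)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
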