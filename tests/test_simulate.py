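"""Synthetic-data generator: genomes, features, timing, insertions, reads."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from ty5cards import (
    Enrichment,
    FeatureClass,
    SimParams,
    annotate_features,
    generate_genome,
    sample_insertions,
    simulate_library,
    synth_timing,
)
from ty5cards.features import FeatureAnnotation
from ty5cards.simulate import SimTruth, TrueInsertion, write_fastq


class TestGenerateGenome:
    def test_deterministic_for_fixed_seed(self):
        g1 = generate_genome(1, [10_000], 0.38, seed=7)
        g2 = generate_genome(1, [10_000], 0.38, seed=7)
        assert g1.chromosomes == g2.chromosomes

    def test_different_seeds_differ(self):
        g1 = generate_genome(1, [10_000], 0.38, seed=7)
        g2 = generate_genome(1, [10_000], 0.38, seed=8)
        assert g1.chromosomes != g2.chromosomes

    def test_lengths_and_names(self):
        g = generate_genome(2, [5000, 8000], 0.5, seed=1)
        assert g.lengths == {"chr1": 5000, "chr2": 8000}

    def test_gc_within_binomial_bound(self):
        # observed GC within 3 sd of Binomial(100000, 0.38):
        # sd = sqrt(n p (1-p)) ~ 153.5 bases
        n, p = 100_000, 0.38
        g = generate_genome(1, [n], p, seed=3)
        gc = sum(b in "GC" for b in g.sequence("chr1"))
        assert abs(gc - n * p) <= 3 * math.sqrt(n * p * (1 - p))

    @pytest.mark.parametrize("bad", [[500], [999, 5000]])
    def test_short_chromosome_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_genome(len(bad), bad, 0.4, seed=0)

    def test_bad_gc_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(1, [2000], 1.5, seed=0)


class TestAnnotateFeatures:
    def test_spacing_and_count(self, small_genome):
        ann = annotate_features(
            small_genome, {FeatureClass.ACS_CONFIRMED_LIKELY: 8}, spacing_min=2000, seed=3
        )
        ivs = ann[FeatureClass.ACS_CONFIRMED_LIKELY]
        assert len(ivs) == 8
        gaps = [b.start - a.end for a, b in zip(ivs, ivs[1:])]
        assert all(g >= 2000 for g in gaps)
        # ACS sites carry the 11 bp consensus width
        assert all(iv.end - iv.start == 11 for iv in ivs)

    def test_zero_counts_give_empty_classes(self, small_genome):
        ann = annotate_features(small_genome, {FeatureClass.ORC1: 0}, 1000, seed=1)
        assert ann[FeatureClass.ORC1] == []

    def test_infeasible_packing_raises_capacity_error(self):
        g = generate_genome(1, [10_000], 0.4, seed=0)
        # pigeonhole: at 2 kb spacing a 10 kb chromosome fits at most 5 sites
        with pytest.raises(ValueError, match="ACS_CONFIRMED_LIKELY"):
            annotate_features(g, {FeatureClass.ACS_CONFIRMED_LIKELY: 60}, 2000, seed=0)

    def test_sites_stay_on_genome(self, small_genome, small_annotation):
        small_annotation.validate_against(small_genome)


class TestSynthTiming:
    def test_formula_at_stated_points(self, small_genome):
        t = synth_timing(small_genome, {"chr1": [5000]}, fork_rate=1000, t0=10)
        assert t.value_at("chr1", 5000) == 10
        assert t.value_at("chr1", 6000) == 11

    def test_equidistant_point_between_two_origins(self):
        g = generate_genome(1, [11_000], 0.4, seed=1)
        t = synth_timing(g, {"chr1": [0, 10_000]}, fork_rate=1000, t0=10)
        assert t.value_at("chr1", 5000) == 15

    def test_matches_bruteforce_minimum_over_origins(self, small_genome):
        rng = np.random.default_rng(9)
        origins = sorted(rng.choice(20_000, size=6, replace=False).tolist())
        t = synth_timing(small_genome, {"chr1": origins}, fork_rate=700, t0=8, t_max=70)
        pos = rng.choice(20_000, size=200, replace=False)
        for p in pos:
            expected = min(8 + abs(int(p) - o) / 700 for o in origins)
            assert t.value_at("chr1", int(p)) == pytest.approx(min(expected, 70), abs=1e-12)

    def test_chromosome_without_origin_rejected(self, small_genome):
        with pytest.raises(ValueError):
            synth_timing(small_genome, {}, fork_rate=1000, t0=10)


class TestSampleInsertions:
    def test_null_model_is_uniform(self, small_genome, small_annotation, flat_timing):
        params = SimParams(n_insertions=2000, timing_tau=math.inf, seed=4)
        truth = sample_insertions(small_genome, small_annotation, flat_timing, params)
        positions = [i.position for i in truth.insertions]
        observed, _ = np.histogram(positions, bins=20, range=(0, 20_000))
        chi2 = sps.chisquare(observed)
        assert chi2.pvalue > 0.01

    def test_acs_enrichment_concentrates_insertions(self):
        # genome large relative to n so the +-100 bp footprint is a small
        # target (without-replacement sampling caps the achievable fraction
        # at footprint/n on small genomes)
        genome = generate_genome(1, [100_000], 0.40, seed=12)
        ann = annotate_features(
            genome, {FeatureClass.ACS_CONFIRMED_LIKELY: 5}, spacing_min=5000, seed=12
        )
        params = SimParams(
            n_insertions=5000,
            feature_enrichment={FeatureClass.ACS_CONFIRMED_LIKELY: Enrichment(50, 100)},
            seed=4,
        )
        truth = sample_insertions(genome, ann, None, params)
        mids = [m for _, m in ann.midpoints(FeatureClass.ACS_CONFIRMED_LIKELY)]
        near = sum(
            any(abs(i.position - m) <= 100 for m in mids) for i in truth.insertions
        ) / len(truth.insertions)
        # uniform expectation: total +-100 bp footprint over genome length
        uniform = len(mids) * 201 / 100_000
        assert near >= 10 * uniform

    def test_enrichment_monotone_in_fold(self, small_genome, small_annotation, flat_timing):
        mids = [m for _, m in small_annotation.midpoints(FeatureClass.ACS_CONFIRMED_LIKELY)]
        fractions = []
        for fold in (1, 5, 25):
            params = SimParams(
                n_insertions=3000,
                feature_enrichment={FeatureClass.ACS_CONFIRMED_LIKELY: Enrichment(fold, 100)},
                seed=13,
            )
            truth = sample_insertions(small_genome, small_annotation, flat_timing, params)
            frac = sum(
                any(abs(i.position - m) <= 100 for m in mids) for i in truth.insertions
            ) / len(truth.insertions)
            fractions.append(frac)
        assert fractions == sorted(fractions)

    def test_timing_coupling_prefers_early_dna(self, small_genome, small_annotation):
        timing = synth_timing(small_genome, {"chr1": [2000, 15_000]}, 400, 5, 70)
        params = SimParams(n_insertions=5000, timing_tau=15.0, seed=21)
        truth = sample_insertions(small_genome, small_annotation, timing, params)
        sampled = np.array([timing.value_at(i.chrom, i.position) for i in truth.insertions])
        genome_mean = timing.genome_mean()
        t = sps.ttest_1samp(sampled, genome_mean, alternative="less")
        assert t.pvalue < 0.01

    def test_empty_request(self, small_genome, small_annotation, flat_timing):
        truth = sample_insertions(
            small_genome, small_annotation, flat_timing, SimParams(n_insertions=0)
        )
        assert truth.insertions == []

    def test_oversized_request_rejected(self, small_genome, small_annotation, flat_timing):
        with pytest.raises(ValueError):
            sample_insertions(
                small_genome, small_annotation, flat_timing, SimParams(n_insertions=30_000)
            )

    def test_deterministic_for_fixed_seed(self, small_genome, small_annotation, flat_timing):
        p = SimParams(n_insertions=500, seed=6)
        t1 = sample_insertions(small_genome, small_annotation, flat_timing, p)
        t2 = sample_insertions(small_genome, small_annotation, flat_timing, p)
        assert t1.insertions == t2.insertions

    def test_positions_unique(self, small_genome, small_annotation, flat_timing):
        truth = sample_insertions(
            small_genome, small_annotation, flat_timing, SimParams(n_insertions=4000, seed=2)
        )
        keys = {(i.chrom, i.position) for i in truth.insertions}
        assert len(keys) == 4000


class TestSimulateLibrary:
    def _one_insertion_truth(self, params, chrom="chr1", pos=10_000, strand="+"):
        n_frag = len(params.enzymes)
        return SimTruth(
            [TrueInsertion(chrom, pos, strand, n_frag, n_frag)], params
        )

    def test_one_read_per_digest(self, small_genome):
        params = SimParams(n_insertions=1)
        truth = self._one_insertion_truth(params)
        reads, stats = simulate_library(small_genome, truth, params)
        assert len(reads) == 3
        assert all(r.sequence.startswith(params.tag) for r in reads)
        assert stats.reads_emitted == 3 and stats.reads_lost == 0

    def test_missing_recognition_site_drops_fragments(self):
        # genome built from a CCGG-free alphabet: every HpaII digest escapes
        from ty5cards import Genome

        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("AT"), size=5000)) + "AAGCTT" + "TCGA" + "A" * 50
        g = Genome.from_dict({"chr1": seq})
        params = SimParams(n_insertions=1)
        truth = SimTruth([TrueInsertion("chr1", 100, "+", 3, 3)], params)
        reads, stats = simulate_library(g, truth, params)
        assert stats.fragments_dropped == 1  # the HpaII fragment
        assert len(reads) == 2

    def test_read_conservation(self, small_genome, small_annotation, flat_timing):
        params = SimParams(n_insertions=300, seed=8)
        truth = sample_insertions(small_genome, small_annotation, flat_timing, params)
        reads, stats = simulate_library(small_genome, truth, params)
        planned = sum(i.n_reads for i in truth.insertions)
        assert stats.reads_emitted == len(reads) == planned - stats.reads_lost

    def test_byte_identical_rerun(self, small_genome, small_annotation, flat_timing, tmp_path):
        params = SimParams(n_insertions=100, seed=17)
        truth = sample_insertions(small_genome, small_annotation, flat_timing, params)
        files = []
        for name in ("a.fastq", "b.fastq"):
            reads, _ = simulate_library(small_genome, truth, params)
            write_fastq(reads, tmp_path / name)
            files.append((tmp_path / name).read_bytes())
        assert files[0] == files[1]


class TestTruthRoundTrip:
    def test_tsv_round_trip(self, small_genome, small_annotation, flat_timing, tmp_path):
        params = SimParams(n_insertions=50, seed=3)
        truth = sample_insertions(small_genome, small_annotation, flat_timing, params)
        truth.to_tsv(tmp_path / "truth.tsv")
        back = SimTruth.from_tsv(tmp_path / "truth.tsv", params)
        assert back.positions() == truth.positions()
        assert {(i.chrom, i.position): i.n_reads for i in back.insertions} == {
            (i.chrom, i.position): i.n_reads for i in truth.insertions
        }
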