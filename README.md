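# ty5cards

Transposon calling-cards analysis for mapping where a chromatin-associated
protein binds the budding-yeast genome.

In the calling-cards method, a protein of interest is fused to the Sir4
domain that recruits the Ty5 retrotransposon integrase, so each Ty5
insertion leaves a permanent, sequenceable mark at a genomic site the
protein visited.  Junction fragments flanking every insertion are recovered
by a three-enzyme restriction digest (HindIII / HpaII / TaqαI),
intramolecular ligation and inverse PCR, then sequenced.  `ty5cards`
implements the downstream analysis for studying DNA-replication proteins
such as the Cdc7 kinase (the catalytic subunit of Dbf4-dependent kinase,
which fires replication origins), together with a full synthetic-data
generator so every stage is testable without any external download.

## What it computes

- **Insertion calling.**  Junction reads are trimmed of the Ty5 terminal
  tag, placed on the reference by exact match over both strands (or
  imported from an existing SAM alignment), and collapsed by
  (chromosome, position, strand) into deduplicated insertion events with
  supporting-read counts.
- **Two normalizations.**  The RPM track gives the quantitative signal at
  position *p*, `RPM(p) = 10⁶ · reads(p) / N_aligned`; the unique-insertion
  track is the 0/1 indicator of whether any insertion occurred at *p*,
  erasing inverse-PCR amplification bias and keeping positional
  information only.
- **Replication-timing windows.**  Using a per-position T_rep profile (the
  time in S phase at which half the cells have replicated a locus), the
  genome is partitioned into 5-minute windows and the mean per-position
  signal computed per window; per-window differences between constructs are
  tested with the two-sided Wilcoxon rank-sum test (exact by enumeration
  for small samples, tie-corrected normal approximation otherwise) and
  banded as `*` (0.01–0.05), `**` (0.001–0.01), `***` (<0.001) or `NS`.
- **Feature meta-profiles.**  Signal from insertions in DNA replicating
  within the first 30 minutes is averaged in 100-bp bins across windows
  centered on feature midpoints — ±1 kb around ARS consensus sequences
  (ACSs, the 11-bp yeast origin motif, split into confirmed/likely vs
  dubious classes), ±5 kb around Orc1 binding sites and centromeres —
  revealing, e.g., a sharp enrichment within 100 bp of origin centers.
- **Transposition efficiency.**  The plating-assay rate of Ty5 integration
  events per cell: colonies on –His 5-FOA over dilution-corrected total
  viable cells on YPD.
- **Simulation.**  Toy genomes, feature annotations, origin-anchored T_rep
  landscapes, and insertion libraries drawn from a multiplicative model
  (uniform background × exponential enrichment kernels around feature
  midpoints × `exp(−T_rep/τ)` timing coupling), rendered into FASTQ
  junction reads through the three-enzyme digest / inverse-PCR model with
  log-normal per-insertion amplification.

## Worked example

```python
from ty5cards import FeatureClass, feature_profile, rpm_track, timing_window_signal
from ty5cards.pipeline import SimulateConfig, build_scenario, simulate_and_call

cfg = SimulateConfig(seed=1)          # 250 kb genome, 5000 insertions,
                                      # ACS enrichment 50x, timing tau 15 min
genome, annotation, timing, truth, insertions = simulate_and_call(cfg)
print(f"called {len(insertions)} insertion events "
      f"from {insertions.total_aligned_reads} aligned reads")

rpm = rpm_track(insertions)
for w in timing_window_signal(rpm, timing, 5.0)[1:5]:
    print(f"T_rep [{w.t_lo:>4.0f},{w.t_hi:>4.0f}) min: "
          f"mean RPM/bp = {w.mean:.2f}  ({w.n_tracked} insertion positions)")

prof = feature_profile(rpm, annotation[FeatureClass.ACS_CONFIRMED_LIKELY],
                       genome.lengths, flank=1000, bin_width=100)
print(f"ACS meta-profile peak at {prof.argmax_offset():+.0f} bp from the ACS center")
```

prints

```
called 4997 insertion events from 34058 aligned reads
T_rep [   5,  10) min: mean RPM/bp = 10.50  (2339 insertion positions)
T_rep [  10,  15) min: mean RPM/bp = 3.90  (851 insertion positions)
T_rep [  15,  20) min: mean RPM/bp = 3.10  (698 insertion positions)
T_rep [  20,  25) min: mean RPM/bp = 2.80  (554 insertion positions)
ACS meta-profile peak at -50 bp from the ACS center
```

The window means fall from the earliest-replicating window outward — the
construct binds early-replicating DNA — and the meta-profile peaks in the
bin touching the origin midpoint, i.e. the integration signal concentrates
within 100 bp of the ACS center.

The same workflow is available from the shell:

```bash
ty5cards all --seed 1 --out-dir out/          # simulate + analyze end to end
ty5cards simulate --seed 1 --out-dir out/sim  # bundle: FASTA, FASTQ, truth TSV,
                                              #   features BED, timing bedGraph
ty5cards call --genome g.fa --fastq reads.fastq --out-dir out/called
ty5cards efficiency --foa-colonies 500 --total-viable 1000000
```

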