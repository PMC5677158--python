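# Methods

## The measurement being modeled

Calling cards converts transient protein–chromatin contacts into permanent
genomic marks: a fusion of the study protein to a Sir4 fragment recruits
the Ty5 integrase, and each integration deposits the transposon at a site
the protein occupied.  The sequencing readout is a junction library: for
each insertion, genomic DNA is digested with one of three enzymes (HindIII
`AAGCTT`, HpaII `CCGG`, TaqαI `TCGA`), circularized, and inverse-PCR
amplified outward from the transposon, so each read begins with a fixed
transposon terminal sequence followed by the genomic DNA 3′ of the
junction.  The three digests of one strain are pooled into a single
library.

## Coordinate conventions

All coordinates are 0-based, half-open, and only converted at the SAM
boundary (1-based) on import.  An insertion's position is the coordinate
of the first genomic base 3′ of the Ty5 junction on the reference plus
strand; this is single-base, strand-resolvable, and is exactly the first
genomic base of the sequenced fragment.  For a minus-strand insertion the
fragment runs leftward on the plus strand, so a fragment matching the
reverse strand over span `[a, b)` places the junction at `b − 1`.  Events
are keyed by (chromosome, position, strand): the two orientations are
distinct integration events, though tracks collapse strand because
bedGraph display is unstranded.

## Insertion placement model (simulator)

The per-base sampling weight is multiplicative:

    w(p) = r_bg · Π_c [1 + (e_c − 1)·exp(−d_c(p)/λ_c)] · exp(−T_rep(p)/τ)

where `d_c(p)` is the distance to the nearest class-c feature midpoint,
`e_c ≥ 1` the fold enrichment with decay length `λ_c` (bp), and `τ`
(minutes) couples placement to replication timing (`τ = ∞` disables it;
smaller τ concentrates insertions in early-replicating DNA).  Positions
are drawn **without replacement** proportional to `w` via the Gumbel
top-k trick, strands are fair coins, and each insertion receives a
log-normal amplification factor `a = max(1, round(LogNormal(μ, σ)))`
modeling inverse-PCR duplication; its total read count is
`n_fragments · a` split evenly over the digests.  Without-replacement
sampling means the realized fraction of insertions inside a small region
saturates at (region size)/n; the closed-form expectation used by the
parameter-recovery checks therefore uses the Poissonized inclusion
probability `1 − exp(−t·w(p))` with `t` solved so inclusions sum to n,
rather than the naive `n·w/Σw`.

Fragment recovery is simplified to the informative junction-side fragment:
for each enzyme, the genomic sequence from the insertion point to the
nearest downstream recognition site on the insertion strand (the rest of
the inverse-PCR circle carries no positional information).  A digest with
no downstream site before the chromosome end drops its fragment and its
read share; both are counted so read accounting closes exactly
(`emitted = Σ n_reads − lost`).  Reads are `tag + fragment` truncated to
the read length, constant quality `I`; there is no sequencing-error model,
so the built-in mapper can be exact.

### Default scenario

A 250 kb two-chromosome genome at GC 0.38 (yeast-like); 24 confirmed/likely
ACS sites of the 11-bp consensus width, 12 dubious ACSs, 24 Orc1 sites, 2
centromeres, 40 TSSs, all ≥ 2 kb apart; every third confirmed/likely ACS
fires as a timing origin with forks at 500 bp/min from t₀ = 5 min (T_rep
capped at 70 min), giving T_rep spanning roughly 5–45 min across 8–9
five-minute windows; 5000 insertions with ACS enrichment e = 50, λ = 100 bp
and τ = 15 min; PCR log-normal μ = 0.5, σ = 0.8 (mean multiplicity ≈ 2.3,
heavy right tail); 50-bp reads with a 20-bp synthetic tag.  These sizes
keep a full simulate–call–analyze cycle at a few seconds while leaving
every window and profile well populated; enrichment and coupling magnitudes
are in the range that reproduces the qualitative structure of real
replication-factor calling-cards data (sharp origin-proximal peaks, strong
early-replication bias).

The generator emulates the statistical structure the analysis assumes —
feature-proximal enrichment, timing coupling, amplification bias, digest
geometry — but not sequencing errors, mappability structure, repeat
families, Ty5 sequence preference, or chromatin accessibility.  Passing
tests therefore certify the analysis machinery, not the biology of any
real library; real data should enter through the SAM import path after
alignment with a mismatch-tolerant aligner.

## Insertion calling

Reads whose prefix matches the tag within a configurable Hamming distance
(default 0) are trimmed; fragments shorter than 18 bp are set aside as
too short to place uniquely.  Mapping is exact substring lookup over both
strands via a 12-mer seed index with verification; exactly one occurrence
is required (a palindromic fragment matching one locus on both strands is
ambiguous and counted as multi-mapping).  Multi-mapping reads are
discarded — a calling card must certify a single location.  Unique
mappings are grouped by (chrom, position, strand); deduplication is by
insertion coordinate only, not fragment end, because the three digests
produce different fragment ends for the same insertion.  Every read lands
in exactly one QC status (UNIQUE / MULTI / UNMAPPED / NO_TAG / TOO_SHORT)
and the counts reconcile with the input.

## Normalization

RPM: `10⁶ · reads(p) / N_aligned` with `N_aligned` the count of
uniquely-mapped reads in the library (multi-mapped and rejected reads are
excluded from the denominator).  Values are formed as reduced rationals
before float conversion so that uniformly duplicating every read leaves
the track bit-identical.  Unique-insertion mode is the 0/1 indicator per
position; its downstream summaries (window and bin means) are what "mean
number of unique insertions" refers to — no further scaling constant is
applied.

## Window and profile statistics

Both summaries use the **mean per genomic position including zeros**
(signal mass / positions covered).  This makes RPM and unique tracks
comparable across window extents and bin widths, and it is what lets
coupling to replication timing register at all: the per-position values at
insertion sites alone are timing-independent under the placement model, so
a tracked-positions-only mean would be flat by construction.

- Timing windows are left-closed (`[0,5), [5,10), …`), the last open-ended,
  so every position lands in exactly one window.  Empty windows are
  reported with n = 0.
- The 30-minute filter keeps events whose position has T_rep ≤ 30 min but
  leaves the RPM denominator at the whole library, since the normalization
  refers to library size, not to the subset.  It applies to all feature
  meta-profiles (ACS, Orc1, centromere, TSS) when timing data are present.
- Meta-profile bins tile `[−flank, +flank)` around the feature midpoint
  (offsets unstranded); sites whose window would cross a chromosome end
  are dropped and counted, never zero-padded, because padding biases bin
  means toward zero.  The central fold ratio between two profiles is the
  ratio of their mean bin values over ±100 bp; 0/0 is flagged NaN.

## Rank-sum testing

Two-sided Wilcoxon/Mann–Whitney with midranks.  The statistic reported is
`U = min(U₁, U₂)`.  For pooled n ≤ 16 the p-value is exact:
`P(min(U₁,U₂) ≤ U_obs)` over all `C(n₁+n₂, n₁)` labelings (≤ 12,870
enumerations, instant, and correct under ties); beyond that, the normal
approximation with tie-corrected variance and a 0.5 continuity correction,
whose error at the switch point (≈ 0.01 absolute at n₁ = n₂ = 8) is below
the resolution of the significance bands.  Window comparisons test the
zero-inclusive per-position value lists, are flagged untestable (not an
error) when a window is empty, and are deliberately not multiplicity
corrected, matching the per-window star presentation convention; a
Benjamini–Hochberg option would be a thin wrapper if needed.

Efficiency: `rate = FOA colonies / (YPD viable count × dilution factor)`,
events per cell; scale-invariant in the two counts; rates above 1 are
rejected as dilution-accounting errors.

## Numerical and degenerate-input choices

- All randomness flows through one `numpy.random.default_rng(seed)` per
  operation; identical calls are byte-identical, including written files.
- Feature placement uses an even per-chromosome lattice with jitter
  bounded so the minimum spacing always holds; infeasible packings raise a
  capacity error naming the class (pigeonhole on length / pitch).
- `T_rep(p) = t₀ + min_o |p − o| / fork_rate`, capped; a chromosome with
  no origin is a configuration error rather than silently late-replicating.
- Zero insertions, empty windows, empty event sets and header-only
  bedGraphs are all valid objects, not errors; zero aligned reads is an
  error only where it would be a division (RPM).
- An insertion whose three digests all escape (no recognition site
  downstream, e.g. at a chromosome edge) legitimately vanishes from the
  library; the simulator logs it, and round-trip recovery is exact
  whenever at least one digest of each insertion yields a mappable
  fragment ≥ 18 bp.

## Known limitations

Exact-match mapping cannot place reads with sequencing errors (use the SAM
import path for real data).  The simulator's timing landscape is a pure
distance-to-origin cone field; real T_rep reflects stochastic origin
firing and efficiency, so absolute window occupancies differ from any real
genome.  Tracks hold single-base signal only; no smoothing, peak calling
or bigWig export.
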