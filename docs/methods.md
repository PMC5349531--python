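# Methods

## Read model and quality filtering

A read is modeled as the concatenation
`[barcode][homology][UMI][tag]` with default lengths 10 / 20 / 8 / 7 nt
and homology `GCAGTGGTATCAACGCAGAG`.  The homology region is located by
a substitution-only scan over all offsets; the leftmost offset achieving
the minimal Hamming mismatch count wins, and the read is rejected if
that minimum exceeds 2.  Substitution-only matching (no indels) was a
deliberate choice: it makes every placement decision a pure Hamming
comparison, hence deterministic, order-independent and directly testable
against an exhaustive-scan oracle.  An approximate matcher tolerating
indels would recover a small additional fraction of reads at the price
of ambiguous anchor coordinates.

`N` bases count as mismatches in the homology scan; an `N` inside the
barcode, UMI or tag segment rejects the read (`ambiguous_base`), keeping
all downstream sequence sets over the {A,C,G,T} alphabet.  Tag matching
is exact by default; a ≤ k-mismatch mode exists (unique-best-hit
semantics) but is off because the two default tags sit at Hamming
distance 3 and exact matching already captures error-free reads.

The barcode length defaults to 10 nt and is configurable; coordinates
are 0-based, half-open throughout.

## Group filters

**Knee filter.** The "inflection point" of the descending barcode
read-count distribution is implemented as the minimal prefix whose
cumulative read share reaches a threshold (default 0.95).  This rule is
deterministic, monotone in the threshold, and matches the stated
~95 %-of-reads retention criterion; a curvature-based detector
(`knee_index_curvature`, maximal distance to the log-log chord) is
provided for exploration but is not the default.  A float-roundoff guard
of 1e-9 reads keeps exact boundaries (e.g. counts summing exactly to the
target) on the retained side.

**Mapping-fraction filter.** Groups are kept when mapped reads /
total reads is *strictly* greater than 0.9, so a group at exactly 90 %
is removed.

**Hamming isolation filter.** Barcodes are clustered by connecting
pairs at Hamming distance exactly 1 (distance 0 cannot occur among
unique barcodes); any connected component of size ≥ 2 is discarded
wholesale — no parent/child merging or read rescue, because connected
clusters are interpreted as cumulative PCR-mutation artifacts whose read
mixtures cannot be trusted.  Components are found by enumerating all 3·L
single-substitution variants of each barcode against a hash set, which
is provably equivalent to the O(n²) all-pairs construction (and tested
against it).  The filter runs on the post-knee, post-mapping-fraction
retained set (the narrative order of the workflow); both the order of
the first two filters and the filter set are configurable.

A side effect worth knowing: two *genuine* barcodes that happen to lie
at Hamming distance 1 are both discarded.  At ~10⁴ cells over the 4¹⁰
barcode space the expected number of such chance-adjacent pairs is
n(n−1)/2 · 30/4¹⁰ ≈ 1.4 per 10⁴ cells — a negligible, deliberate loss.

## UMI deduplication and classification

Within one cell, the count for antibody *a* is the number of *distinct*
UMI sequences among reads mapping to *a*; UMIs are never collapsed
across antibodies.  Exact-unique counting is the default; an optional
Hamming-1 UMI merging mode (connected-component counting) exists for
error-rich data but undercounts when true UMIs collide, so it is off by
default.  With 8-nt UMIs the collision loss is tiny: a cell with 20
molecules expects C(20,2)/4⁸ ≈ 0.003 colliding pairs.

A cell is positive for marker *m* when its UMI count reaches the
positive threshold, default **5** distinct UMIs.  No threshold is
prescribed by the underlying workflow ("strongly expressed" is the only
guidance); 5 was chosen once as the midpoint on the log scale between
the expected off-target signal (≈ 0.2 UMIs) and on-target signal (≈ 20
UMIs per cell), and is exposed as `--positive-threshold`.  Cells
positive for exactly one marker are labeled `<m>+`, for two or more
`double_positive`, and for none `negative` (reported, never dropped).

## Design arithmetic

Capacity identities: C = N_c · N_r and dynamic range = C/(N_c · N_a),
exact by construction.  Poisson occupancy uses `expm1` for the
1 − e^(−λ) term so the multiplet rate is stable down to λ → 0.  The
expected mixed-type multiplet fraction treats each encapsulated cell's
type as an independent Bernoulli(p) draw:
Σ_{k≥2} P(k; λ)(1 − p^k − (1−p)^k) / P(≥1; λ), with the series truncated
when the Poisson weight falls below 1e-12 (absolute), far beyond any
reported precision.

## The simulator

The generator emulates the droplet workflow at the study conditions,
which are its defaults: merge events load cells at λ = 1/30 and clonal
barcode molecules at λ = 1/10 (both Poisson); cell types are a 69:31
two-type mixture with near-binary marker expression — Poisson molecule
counts with on-target mean 20 (the typical recovered UMIs per cell) and
off-target mean 0.2; UMIs are uniform random 8-mers; cell barcodes are
drawn uniformly *without replacement* from the 4¹⁰ space.  When an event
holds ≥ 2 barcode droplets, molecules are split uniformly across
barcodes (the split-cell artifact).

PCR amplification is modeled as 1 + Geometric extra copies per molecule
with mean `amplification_mean` (default 30, giving ~600 reads per cell
before any subsampling — a deliberately saturating depth so UMI
deduplication is exercised).  This single-knob shifted-geometric model
reproduces the long-tailed duplicate-UMI histogram of real libraries;
cycle-by-cycle branching PCR is out of scope.  GC bias enters as a
linear multiplier on the amplification mean,
`1 + β·(GC(barcode) − 0.5)`, clamped at zero; β defaults to 0 so the
null simulator is unbiased.  Substitution errors are applied per copy
(`pcr_substitution_rate`) and then per read (`seq_error_rate`), both 0
by default; indels and quality-score profiles are not modeled.  All
randomness flows from one seeded NumPy generator, so a fixed seed yields
byte-identical FASTQ and truth files.

What passing tests on simulated data do **not** show about real data:
the simulator has no ambient/contaminating DNA (the mapping-fraction
filter is only exercised synthetically), no droplet-merger failures, no
indels, and flat base quality; real knee positions and error structures
will differ.

## Problem sizes used in tests

End-to-end suites simulate 20,000–30,000 merge events (≈ 60–100 barcoded
cells, ≈ 40,000–60,000 reads) — large enough that binomial 3-SE checks on
the recovered 69:31 mixture are meaningful, small enough to keep the
suite fast.  Encapsulation statistics are checked on 10⁶ events against
the closed forms; the acceptance script uses 4 × 10⁶ events so the
Monte-Carlo standard error on the mixed-multiplet percentage (~0.02
percentage points) is negligible relative to the quantity itself.
Zero-noise end-to-end runs use a knee threshold of 1.0 because error-free
data has no artifact tail for the 0.95 rule to trim.

## Known limitations

- Whole-component discarding cannot recover reads from mutated barcodes;
  a rescue/merging mode is explicitly out of scope.
- The positive-call threshold is a step function; no mixture-model or
  background-aware calling is attempted.
- The homology filter does not tolerate indels (see above).
- Population fractions are reported over all cells passing filters;
  split cells (one cell, two barcode droplets) appear as two
  lower-count cells and are not re-merged.
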