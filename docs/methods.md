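# Methods

## Motif taxonomy

A microsatellite unit is equivalent to its cyclic rotations and, because
loci live on duplex DNA, to the rotations of its reverse complement. The
canonical representative of a class is the lexicographic minimum
(A < C < G < T) over that orbit of at most 2·k strings. Lexicographic-first
is our convention; no universal standard exists, but it matches the
alphabetical labels commonly used in genome surveys (AC rather than GT, AAG
rather than CTT). Non-primitive units — whole-number powers of a shorter
unit — are re-expressed in their primitive unit before classification, so
an ACAC hit is a dinucleotide AC locus. Class enumeration walks all 4^k
strings, drops non-primitive ones and buckets by canonical form; it is
computed, never hard-coded. The counts for k = 1..6 are 2, 4, 10, 33, 102,
350.

AT-richness of a unit is the count p of A/T bases, labelled
`[(A/T)_p, X_q]`; a class is called AT-rich when at most one base is G or C
(q ≤ 1), the binning under which AT-rich trimer classes hold 92% of perfect
trimer loci in the packaged genome-survey counts.

## Repeat scanner

The scanner is a deterministic seed–extend–score detector, scoring-compatible
with the Tandem Repeats Finder (TRF) parameter conventions but intentionally
not a clone of TRF's probabilistic model; we make no claim of locus-level
numeric identity with TRF output on real genomes.

1. **Seeding.** For each period p ∈ {2..6}, maximal runs of self-matches
   `s[i] == s[i+p]` of length ≥ p mark candidate arrays. Runs separated by
   gaps ≤ p + 3 are merged, which bridges isolated substitutions (each
   breaks two self-match positions) and single short indels (which shift
   the comparison phase over a window of about p bases).
2. **Unit.** The candidate unit is read off the start of the seed run; if it
   is non-primitive the candidate is dropped, because the primitive period's
   own scan reports the array.
3. **Scoring.** The candidate region (padded by one unit left, two right) is
   aligned locally against the cyclic extension of the unit by wraparound
   dynamic programming: +match_weight per matched base, −mismatch_weight per
   mismatch, −indel_weight per inserted/deleted base, with local resets, and
   the best-scoring segment is reported. A perfect array of span L therefore
   scores exactly match_weight × L — the first copy counts as matched
   against the wraparound pattern. `percent_match` is matched/(matched +
   mismatched) over the alignment and `percent_indels` is the indel share of
   aligned columns, both rounded to integers; `copy_number` is the aligned
   span divided by the unit length, to one decimal.
4. **Filtering.** Emission requires score ≥ min_score and copy number ≥
   min_copies (default 3). Among loci sharing ≥ 50% of the shorter span, the
   highest score wins; ties break to smaller unit length, then leftmost
   start. N runs never participate: sequences are split at them and chunks
   scanned independently.

Presets: *strict* = weights {2,3,5}, min score 50 (favours short perfect
arrays); *loose* = {2,7,7}, min score 20 (admits longer, degenerate arrays).
Detection boundaries can differ from the planted truth by a base or two
where background happens to extend an array; benchmarks therefore assert
≥ 90% reciprocal overlap with truth intervals, not exact coordinates.

Composition summaries count loci per canonical class split by perfection,
report loci per megabase, and report the genome fraction with overlapping
locus spans collapsed before summing so no base is counted twice (published
genome-fraction figures do not state their overlap handling; collapsing is
our choice). The tallies-only constructor supports published per-class
counts when the loci themselves are unavailable.

## Mutation calling

MA lines are treated as haploid-equivalent: a selfing hermaphrodite
propagated through single-individual bottlenecks fixes each new allele
essentially immediately, and all assessed loci are homozygous. The signed
repeat-unit change is `(allele_bp − progenitor_bp)/unit_length`; a
difference that is not a multiple of the unit length is an off-ladder
artifact — logged and suppressed rather than called, since bench practice
re-verifies such fragments. Missing genotypes produce no call and reduce
that marker's assessed-line count l, which is reported alongside every rate.

Spectrum conventions:

- `n_per_marker` (the estimator's n) counts **distinct mutated lines**, not
  events; the two coincide in the packaged panel, where no line mutated
  twice at one marker.
- The insertion-vs-deletion comparison (23 vs 8 in the panel) is a count of
  **events**, not a sum of repeat units; the panel's unit sums would be
  26 vs 19.
- "Long" in the perfect/long stratification means repeat count > 3 — the
  smallest threshold that isolates the one 3-unit mutated locus — and is a
  parameter, not a constant.
- Per-locus trend is the sign of the summed unit changes. One panel locus
  (M88, calls −1, −1, −2) nets −4 and is classified *decrease*, although
  the source narrative describes it as unchanged; we follow the arithmetic
  of its transcribed calls.

## Rate estimation

Zero-class estimator: with mutations Poisson at rate µ per allele per
generation, a line is unmutated after t generations with probability
e^(−µt), so µ̂ = −ln(1 − n/l)/t. It is exactly 0 at n = 0, exceeds the naive
n/(l·t) (the log corrects for multiply-mutated lines; the relative gap is
≤ 3% while n/l ≤ 0.05), and is undefined at saturation n = l, which raises
an error; batch estimation records the error and continues. Estimates from
a single mutated line are emitted but flagged: one event cannot support a
proper frequency. Per-marker assessed-line counts are data, never silently
assumed to equal the experiment-wide line count.

Confidence intervals are exact Clopper–Pearson binomial bounds on the
mutated-line fraction pushed through the monotone map µ = −ln(1−f)/t
(scipy beta quantiles); coverage is validated by simulation to within 5
percentage points of nominal.

`suggested_rate` averages µ̂ over perfect markers with ≥ 30 repeat units and
≥ 2 mutated lines — the marker population recommended for divergence
dating. It is a reporting convention, not a statistical estimator, and is
labelled as such in output.

## Synthetic data

The simulator emulates the fixture experiment's design: 82 lines (optionally
100 with uniform-random attrition to 82), 142 generations, per-locus rate µ.
Each line × locus × generation mutates with probability µ; the step is ±1
with probability 26/31, otherwise a multistep magnitude 1 + Geometric(q)
with q = 1/3 (mean multistep magnitude 4, matching the observed multistep
magnitudes 2, 3, 3, 9 whose mean is 4.25; no published distribution exists,
so the geometric tail is our convention). The sign is an insertion with
probability 23/31, independent of magnitude. Repeat counts floor at 3
units: a deletion that would cross the floor is redrawn, so loci cannot die
— the fixture experiment observed no locus death. Allele sizes are
repeat-tract length plus a fixed 100 bp flank, standing in for PCR-product
geometry. Fixation is instantaneous; culture details of the real experiment
(backup generations, F3 initiation) are irrelevant to the mutation model
and not simulated.

Planted-repeat genomes use i.i.d. background at a given A+T fraction
(default 0.58, a typical AT-rich nematode genome). What this does **not**
emulate: chromosomal heterogeneity, cryptic simplicity around real arrays,
GC-content gradients, stutter noise in genotyping, or length-dependent µ
within a run (a hook exists but no default model is claimed). Passing
recovery tests on these genomes shows the scanner and estimator are correct
under the stated model, not that real-genome screens would reproduce any
particular published locus table.

Determinism: all randomness flows from one `numpy.random.default_rng(seed)`;
identical configs and seeds give byte-identical outputs.

## Problem sizes and numerical choices

Simulation-based tests use 500 replicate loci for parameter recovery (mean
µ̂ within 3 standard errors of truth at µ ∈ {1e-4, 5e-4}) and 1000 replicates
for CI coverage — sizes at which the binomial bounds being tested are sharp
while the whole suite runs in seconds. Scanner benchmarks use 1–8 kb
genomes with planted arrays spanning the panel's unit lengths. Degenerate
inputs: empty sequences and empty call lists yield empty results, not
errors; an empty genome with requested plants is an error; genome fraction
of a zero-length genome is 0.

## Known limitations

- The scanner's percent-match semantics differ in detail from TRF's; strict
  and loose presets match TRF parameters in spirit, not bit-exactly.
- Per-marker published rates cannot all be reproduced exactly because the
  source's per-marker assessed-line counts are unpublished; the estimator is
  validated by closed form and simulation instead, and the fixture
  realization sets l = 82 everywhere.
- Heterozygous/diploid genotypes and PCR stutter are out of scope (selfing
  organism, homozygous loci).
- Homoplasy (+1 then −1) hides events; the pipeline's totals are a lower
  bound on true event counts, as the round-trip tests assert.
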