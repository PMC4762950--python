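# Methods

`igdiv` implements the computational side of an Ig-gene diversification
experiment in DT40-style B cells: counting somatic hypermutation (SHM) and
gene conversion (GCV) events in sequenced amplicons, detecting
single-stranded-DNA patches in bisulfite reads, quantifying transcription
elongation from ChIP coverage, and summarizing GFP-loss fluctuation assays.
Because experiments of this kind rarely deposit their raw Sanger and
flow-cytometry data, the package pairs every analysis with a synthetic-data
generator that plants known events, so each caller can be validated by truth
recovery and by independent brute-force oracles.

## Mutation-event calling and clonal correction

Clone amplicons are globally aligned to the reference locus with affine gap
penalties (match +1, mismatch −2, gap open −5, gap extend −1; conservative
for low-divergence Sanger amplicons, configurable). Among co-optimal
alignments, gaps are shifted to their leftmost score-equivalent placement so
indel coordinates are reproducible — this matters because downstream
deduplication keys on exact positions. Terminal gap columns are trimmed: a
read that does not reach the locus boundary is incomplete coverage, not a
deletion. Sequences below 90% identity to the locus are excluded and logged
(off-target amplicons).

Clonal correction follows the standard rule for subcloned cultures: a
mutation present in more than one sequence of a subclone at an identical
position (same alternate allele) arose once in a common ancestor and is
counted once. The rule is applied per subclone, never across subclones.
Identical indels are collapsed the same way, flagged distinctly, since the
same lineage argument applies. The event frequency divides counted events by
the **total** base pairs sequenced, clonal duplicates included, matching how
such frequencies are conventionally reported; note this makes the frequency
an underestimate of the per-lineage rate when duplication is common, which
is why the truth-recovery tests compare counted events against the
distinct-lineage base count.

## Gene-conversion classification

Chicken IgL diversification uses ~25 upstream pseudo-V genes as conversion
donors. A cluster of changes counts as GCV only when the mutated stretch is
base-for-base identical to at least one donor. With positionally homologous
donors (the generator's donors are point-diverged copies of the locus), the
classifier finds, per donor, all maximal reference intervals where the
mutated sequence equals the donor and which contain at least one
donor-vs-locus marker. Substitutions are then assigned greedily: the tract
explaining the most unassigned substitutions wins (ties: shorter interval,
then lowest donor index; all donors explaining the same call set are
retained), as long as it explains ≥ 2 of them. A lone donor-explained
substitution is classed *ambiguous* — with one marker, a templated
conversion and a chance point mutation are indistinguishable, the standard
convention in the DT40 GCV literature. Everything else is a point mutation;
indels pass through as their own categories. Every call lands in exactly one
event, and tests verify the greedy assignment reaches the same minimum event
count as an exhaustive assignment search on small instances.

Events are classified per sequence and then clonally corrected per subclone
with the same identical-event rule as point mutations (identical category,
interval, member calls, and donors count once).

The support threshold of 2 is configurable. The synthetic generator plants
tracts carrying ≥ 2 donor markers by default (`min_tract_markers`): a
1-marker tract is invisible *as a conversion* to any classifier, so planting
them would only convert a knowable truth ledger into an unknowable one. Set
`min_tract_markers=1` to simulate the harder, partially unidentifiable
regime.

## Bisulfite single-stranded-DNA patches

Bisulfite converts cytosines on exposed single-stranded DNA; after PCR the
record is C→T transitions (top strand) or G→A (bottom strand, reported in
top-strand coordinates). Each read is aligned to the locus and every
reference C (or G) is classed converted/unconverted; non-bisulfite
mismatches (e.g. C→A) are excluded from the profile and reported. Identity
filtering is applied after masking transitions so a fully converted read is
still accepted. A patch is a maximal run of ≥ 2 *successive* conversions —
consecutive in the ordered candidate-position list, no intervening
unconverted C/G. Its boundaries are the nearest unconverted candidate on
each side; a run abutting the read end receives a sentinel boundary and is
still counted (the conservative completeness choice), flagged by the
sentinel. Both the run endpoints and the flank positions are reported, so
either reading of "patch extent" (inclusive run vs flanking interval) is
recoverable. The statistic `% ssDNA patches` is 100 × patches / bp
sequenced, reported per strand and combined.

Strand auto-inference requires a ≥ 3:1 majority of C→T over G→A mismatches
(or vice versa); CpG positions are not excluded (chicken amplicons;
methylation would suppress conversion and can be masked explicitly if
needed).

## ChIP elongation index and metagene profile

Coverage is reads-per-million (RPM) per base; windowed wig-style scores sum
RPM over 100-bp windows (step configurable — both overlapping and tiled
emission are supported and recorded in output metadata). The elongation
index is body signal density divided by promoter-proximal density, both in
RPM/kb. For a short reporter cassette the proximal window is TSS ± 100 bp
(half-open `[TSS−100, TSS+100)`) and the body runs from +101 to the end of
the coding region; for genome-annotation genes the proximal window widens to
(−100)–(+300) and the body is +300 to the TTS, strand-aware. A zero proximal
density yields an *undefined* index (never an infinity) and such genes are
excluded from summaries and counted separately. Coordinates are 0-based
half-open internally; BED and bedGraph are read as 0-based half-open,
wiggle as 1-based per its standard and converted on read.

The metagene profile takes each gene from 100 bp upstream of the TSS to the
TTS, splits that span into 100 bins (boundaries at rounded equal fractions;
per-bin density uses each bin's true width so rounding stays unbiased),
computes reads per bp per bin, scales the vector to maximum 1, and averages
over genes — per-gene-then-average, with a pooled-normalization option.
Top-gene selection ranks each sample's genes by score (stable ties: score
descending, id ascending), takes the top N, and intersects across samples.
Percentile placements use the mid-rank convention.

The elongation index, percentiles, and metagene profile are all invariant
to scaling a track by a positive constant and to strand mirroring; the test
suite asserts both.

## Fluctuation assay and statistics

Per-subclone GFP-negative percentages above 50% are excluded before any
summary: such subclones were plausibly GFP-negative at subcloning and
measure the starting state, not fluctuation. Summaries report medians over
retained values, exclusion counts, fold-stimulations as median ratios, and
pairwise Mann-Whitney tests.

The comparisons are: a pooled two-proportion z-test for mutation-event
frequencies (two-sided by default, no continuity correction — negligible at
these denominators, available as a flag); Mann-Whitney with mid-rank ties
(exact enumeration when the smaller group has ≤ 8 values and no ties, else
normal approximation with tie correction, method recorded); and one- or
two-tailed t tests (Welch by default, pooled optional, method recorded —
the appropriate default when variance equality is unverified). No
multiple-testing correction is applied by default; significance bins are
\* p<0.05, ** p<0.01, *** p<0.001, NS otherwise. p-values are always in
[0, 1]; degenerate inputs (pooled proportion 0 or 1, zero variance) are
flagged rather than returning infinities or NaNs.

RT-PCR relative expression averages replicate signals, normalizes the
target to a housekeeping reference (Rab7a in these assays), and reports
fold over a baseline line's normalized value.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical structure* of the assays, not
their chemistry:

- **Clone sets** — amplicons of a 500 bp V-like locus (Poisson point
  mutations per bp; Poisson donor-templated tracts per sequence, 30–60 bp,
  copied from 25 pseudo-V donors diverged 5% per base; exact within-subclone
  duplication with probability ~0.3 emulating clonal lineage structure).
  Defaults of 8 subclones × 40–50 sequences match a realistic Sanger study.
  Not modeled: sequencing error, chromatograms, indel-diverged donors.
- **Bisulfite reads** — planted conversion runs of 2–5 candidate positions,
  separated by an unconverted flank so planted patches never merge, over an
  independent per-C background (0.5%). Not modeled: incomplete conversion
  bias, PCR duplicates.
- **Coverage tracks** — piecewise-constant region densities (promoter
  proximal vs gene body vs flank) with multiplicative gamma noise of a
  given CV (default 0.2, a typical window-level dispersion for ChIP
  coverage). The three stock tracks plant body/proximal ratios of 1.1, 0.05,
  and 0.275 — a strongly elongation-associated factor, its collapse, and a
  partial (5.5×) restoration. Not modeled: read-level counting noise,
  mappability, peak shape.
- **GFP loss** — independent per-generation inactivation: expected negative
  fraction 1 − (1 − r)^g, sampled binomially over 10⁴ cells; 14 generations
  stand in for a 14-day culture. Per-generation rates are chosen to plant
  no-DIVAC medians of ~0.2% (endogenous AID) and ~1% (AID over-expressed,
  5× higher background) with DIVAC stimulations of 9× and 30× — the
  qualitative structure of a DIVAC fluctuation experiment. A
  Luria–Delbrück-style branching option (`jackpot=True`) inflates variance
  with early-loss jackpots; it is off by default because the measurement
  model, not the growth model, is what the assay summaries consume.

Passing truth-recovery tests on these data shows the *rules* are
implemented correctly (clonal correction, exact-match tract logic, run
calling, window arithmetic); it does not certify performance on real reads
with sequencing error, alignment ambiguity, or donor repertoires with
structural divergence.

## Numerical and design notes

- All generators take explicit integer seeds and are bit-reproducible;
  the CLI writes a manifest (parameters, seed, version) per run.
- Event proportions are exact rationals; frequencies are exact fractions
  with a per-10⁴-bp convenience scale.
- Alignment scores are validated against an independent quadratic Gotoh DP;
  patch calling against exhaustive run enumeration; Mann-Whitney against
  full permutation enumeration for all splits with ≤ 10 values; top-gene
  selection against brute-force sort-and-intersect.
- Problem sizes in the analysis scripts and acceptance run (8 subclones ×
  50 sequences × 500 bp per line; 50 bisulfite reads; 10 coverage
  replicates; 10 subclones per fluctuation arm) were chosen as a realistic
  desk-scale study; all complete in seconds.

## Known limitations

- The aligner assumes one reference per run; no multi-locus batching.
- GCV attribution requires positionally homologous (or pre-aligned) donors;
  donor discovery and probabilistic tract assignment are out of scope.
- The two-proportion z-test treats bases as independent Bernoulli trials;
  overdispersion from per-subclone rate variation is not modeled.
- Bisulfite analysis is amplicon-scale; no genome-scale alignment, no
  methylation-rate estimation.
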