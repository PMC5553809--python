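# Methods

## Coordinate conventions

All coordinates are 0-based half-open, on the linear frame [0, G) of a
circular chromosome. Window counts, k-mer indexing and repeat scanning wrap
the origin; called intervals do not (a region spanning the origin is
reported as two linear pieces — see Limitations). Human-readable reports
print 1-based inclusive positions.

## Read preparation

Reads are kept only if every base has Phred quality ≥ `q_min` (default 20,
i.e. ≥ 99% per-base accuracy). Variable-length reads are standardized by
taking the central `target`-length substring (default 50 nt); with an odd
surplus the left offset is `floor((len − target)/2)`. Shorter reads are
discarded. Reads containing N survive filtering but cannot anchor: the
stringency gate of this pipeline is the exact-match requirement, not the
quality filter.

## Anchoring

The genome's every L-mer (top strand, origin-spanning included) is hashed
to its left coordinate. A read matches if it equals a window on either
strand exactly; the anchor is always the left coordinate, so fully
complementary reads collapse to the same position — equivalently, 5' ends
are recorded for top-strand reads and 3' ends for bottom-strand reads. A
read equal to its own reverse complement is one molecule and counts once.
Multi-locus reads add one count at every matching locus under the default
`all-occurrences` policy; this keeps repeated loci (rRNA operons, REP
elements) countable. The `unique-only` policy drops them, mimicking
aligners that ignore multireads.

## Normalization, windows, R

Scaling assumes occupancy is unchanged at most genomic positions: each
per-position profile's mean is computed after removing the 2% highest and
2% lowest position values (zeros included; `scipy.stats.trim_mean`), and
the IP profile is multiplied by ctrl_tm/ip_tm. The trim is positionwise —
the trimmed fraction refers to positions, not to distinct intensity values.

Window counts sum the profile over the w-length window centered at each
position (w odd by default; left-heavy by one for even w), wrapping the
origin. Defaults: w = 35 (of the supported 25/35/75, the mid size best
balances resolution against empty windows at realistic depth), pseudocount
1.0 per window count (guards coverage gaps; echoed in output metadata).

## Peak extraction semantics

A qualifying interval satisfies: length ≥ `min_len` (60 bp, the assumed
size of one occupancy footprint), fraction of positions with R ≥ `r_min`
(1.5) at least `min_frac` (50%, inclusive), and both end positions above
threshold. The caller returns the *containment-maximal* qualifying
intervals — identical to enumerating every interval, applying the
predicate, and keeping those contained in no other qualifying interval.

`min_frac` is parsed from its decimal representation into an exact rational
so the boundary (30 of 60 positions) is integer arithmetic. With the prefix
score S(p) = den·ones([0,p)) − num·p, an interval [x, y) qualifies on the
fraction iff S(y) ≥ S(x); maximal intervals necessarily start at the first
position of a run of above-threshold positions and end at the last position
of such a run, which reduces extraction to monotone queries over run
boundaries (O(m log m) in the number of runs). On rare, precisely balanced
tracks two maximal intervals overlap while their union fails the predicate;
overlaps are resolved deterministically (longest first, then leftmost), and
every emitted peak re-verifies the predicate positionwise.

Unbound regions require R < 1.0 (strict) at *every* position in both
experiments over ≥ 60 bp; fragments shorter than 60 bp after a split are
discarded before any merging. Intervals overlapping a caller-supplied
exclusion set by ≥ 1 bp are removed whole. The merge rule (gap < 30 bp,
all intermediate R ≤ 1.1, iterated to fixpoint) is a separate operation:
the pipeline applies it to unbound regions after calling, using the
positionwise maximum of both experiments' tracks as the intermediate-R
reference, and exposes it as an option for peaks. The combined set removes
whole second-experiment peaks that touch a first-experiment unbound region
by ≥ 1 bp (no clipping); a switch selects absence-of-exp1-peak instead of
UR-overlap as the removal criterion.

## Repeat scanning

A pair (type, i, j) at top-strand position p requires the i-mer arm at p to
be followed after j bases by an identical copy (direct) or its reverse
complement (inverted). Each qualifying (p, i, j) is counted once at its
leftmost coordinate; an inverted pair equals its own mirrored description,
so a single top-strand pass enumerates each pair exactly once, and the
per-cell totals are exactly multiplicative: L_ij = n_ij · (2i + j).
Default ranges: direct i 5–24 / j 0–20, inverted i 5–18 / j 3–20 — pure
configuration, overridable per scan.

`maximality="none"` (default) counts every qualifying triple, keeping the
additive totals identity exact. `arm-maximal` suppresses pairs whose arms
extend by one base to a longer qualifying pair — outward keeping the
alignment (direct: offset-preserving extension into the spacer, j ≥ 1;
inverted: same center, spacer j or j−2) — since the enumeration convention
of interactive repeat-finding tools is generally unspecified; both counts
are reported where it matters.

The scan is vectorized: a direct cell is one circular shift comparison plus
a windowed all-of-i test; an inverted cell uses the fact that paired
indices sum to the constant 2p + 2i + j − 1, making each of the i base
comparisons a fixed shift of the genome against its complement.

## Overlap enrichment

E = (L_elements/G) · L_set is the expected shared base-pair count for
independently, uniformly placed elements; K = O/E. Repeat-vs-set overlap
defaults to the *multiplicity* convention — each footprint intersected
independently, overlapping footprints double-counted — consistent with the
additive L_ij totals; the union convention (merge footprints first) is
available and reported alongside. Set-vs-set fold enrichment always uses
the union convention and is symmetric in its arguments. A Monte-Carlo
repositioning null (uniform restarts on the circle) validates the
closed-form E in the test suite.

Probe tables (start, enrichment ratio) become interval sets by keeping
probes with ratio ≥ 2 (inclusive) and expanding to [start, start + 60);
point coordinates expand to centered width-w intervals (w configurable;
36 for point-coordinate peak-maxima datasets). Overlaps merge.

Per-(i,j) K distributions of two target sets are compared with a two-sided
Mann–Whitney U test (exact U distribution when samples are tie-free and
≤ 25 each, asymptotic otherwise; Welch's t available). All-equal degenerate
input returns p = 1 with a warning.

## Synthetic data generator

The generator emulates: a circular genome with E. coli-like base
composition (GC 0.508 by default), planted repeat pairs (arm written, then
partner copied or reverse-complemented; mutually overlapping planted
footprints are rejected as contradictory), planted occupancy sites as
(interval, factor ≥ 1), an origin-proximal copy-number gradient (linear
decay from a maximum at the origin to 1 at `decay_span`, symmetric on the
circle — replication in growing cells biases raw coverage toward oriC),
uniform fragment lengths on `fragment_range` (default 150–300 bp, one of
the study-style sonication windows), and fixed-length exact reads (50 nt)
emitted from the 5' end of a uniformly chosen fragment strand with constant
Q40 qualities (optional per-base degradation rate for exercising the
quality filter).

IP fragments are enriched multiplicatively when the fragment *overlaps* a
planted site (strongest touched site wins). Under this gating the expected
R at a site center approaches the planted factor, with shoulders decaying
over roughly one fragment length — which is why recovered peaks extend
beyond planted intervals and why truth-matching uses site midpoints (and,
for precision, sites expanded by half the maximal fragment length, the
physical smear scale). Midpoint-gated enrichment was considered and
rejected: for sites shorter than a fragment it caps the attainable R well
below the factor (end-anchored reads sit 75–150 bp from enriched
midpoints), making even factor-2.5 sites undetectable at the R ≥ 1.5
threshold.

Everything is deterministic given (spec, seed): genome, truth and FASTQ
bytes are identical across reruns; independent child streams are derived
for genome, control and IP sampling.

What the generator does **not** model: sequencing errors beyond the optional
quality degradation (reads are exact substrings), PCR duplicates, paired
ends, GC- or mappability-bias, and fragment-size distributions other than
uniform. Passing tests therefore demonstrate the pipeline's correctness and
calibration under its own stated model, not robustness to real-library
artifacts such as adapter contamination or amplification jackpots.

## Validation problem sizes

The suite validates at sizes chosen to keep a full run on one CPU within a
coffee break while leaving no operation untested at scale: oracle
equivalence on ~50 random toy instances (genomes/tracks of 0.25–1 kb);
null calibration at mean anchored depth 20 per position on a 40 kb genome
(mean R within 1 ± 0.05; < 1% of positions inside called peaks);
planted-site recovery at depth 50 on 10 kb genomes across 20 seeds, 4 sites
per seed, lengths 120–220 bp, factors uniform on [2, 6] (≥ 95% recall by
site-midpoint containment and ≥ 95% precision). "Depth" here is the
profile's own coverage — mean anchored reads per genome position — the
regime the method actually operates in (study-scale libraries of tens of
millions of 50-nt reads on a 4.6 Mb chromosome anchor ~7 reads per
position, giving 35-bp window counts in the hundreds). At windowed counts
this large the Jensen bias of the ratio of two noisy counts (≈ μ/ (μ+c)²
per window) is negligible; at sequence-coverage-style depths it would not
be, and the mean-R calibration band would be unattainable for any unbiased
simulator.

## Known limitations

- Called intervals never wrap the replication origin; a genuine
  origin-spanning region appears as two adjacent calls.
- The exact-match index stores every genome L-mer in a Python dict: fine
  for bacterial genomes (~1 GB at 4.6 Mb × 50-mers), unsuitable for large
  eukaryotic genomes.
- No model-based significance for peaks (the ratio thresholds are the
  calling rule); external callers' peak sets enter only as exclusion BEDs.
- Multiplicity overlap counts can exceed the target length when repeat
  footprints pile up; this is intentional (see conventions) but means K is
  not bounded above by 1/coverage-fraction under that convention.
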