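# Methods

This note records the models, parameter choices and numerical decisions
behind `amplikit`, and what the synthetic-data tests do and do not show.

## Alignment model

Global pairwise alignment uses affine gap costs with position-dependent
rates: a gap run in the query is *terminal* exactly when it precedes the
first or follows the last query symbol (rows 0 and m of the dynamic
program), and symmetrically for the target (columns 0 and n). Defaults —
match +2, mismatch −4, interior open/extend 20/2, terminal open/extend
2/1 — follow the drop-in convention of the USEARCH-family tools so that
identity thresholds behave comparably; all are overridable
(`--match/--mismatch/--gapopen/--gapext`, using the `20I/2E` syntax for
interior/end values).

Ambiguity codes: textually equal symbols (after uppercasing and U→T)
count as matches for identity; N against anything scores 0 and counts as
a mismatch; other intersecting IUPAC sets receive the match score but
count as mismatches for identity. This keeps identity a statement about
the written sequences while letting ambiguity codes pair without penalty
during alignment.

Two implementations share one cost model. The full-matrix Gotoh kernel
(numba-compiled, rolling score rows, one byte of traceback per cell)
serves products up to 25,000,000; above that, a Myers–Miller style
divide-and-conquer recursion splits the query at its midpoint, finds the
optimal crossing column from forward and backward score vectors — with
an explicit second candidate for crossings *inside* a vertical gap run,
whose open penalty must not be charged twice — and recurses with
"open-waived" flags at the cut corners. The two paths are verified
against each other, against an exhaustive alignment enumerator at tiny
lengths, and against an independently configured third-party aligner in
the test suite. Traceback ties prefer diagonal, then gap-in-query, then
gap-in-target, so the full-matrix path yields one canonical alignment;
the divide-and-conquer path may return a different optimal alignment
(scores always agree; identities can differ between co-optimal
tracebacks of unrelated sequences, which is why identity equivalence is
asserted on homologous pairs).

One property worth recording: with terminal gaps cheaper than interior
ones, alignment scores are *not* monotone under appending a shared
suffix — a trailing gap loses its terminal discount when a suffix lands
behind it. The monotonicity property test therefore runs under uniform
gap pricing.

## Search heuristic

Words are 8-mers by default (`--wordlength` 3–15); words containing
non-ACGT symbols are skipped, as are words touching soft-masked
(lowercase) positions. Candidate order is shared-word count descending,
target length ascending, target ordinal ascending — a total order
independent of index construction. The per-query threshold is
min(`--minwordmatches`, number of distinct query words), floor 1; with
zero words the query simply gets no hits. Posting lists switch to dense
bitmaps when a word occurs in more than one eighth of the targets plus
eight — purely an internal representation, covered by a test asserting
representation invisibility. Pre-alignment exclusions (`--self`,
`--minqsize`) do not consume a rejection; any post-alignment failure
(identity, `--maxgaps`, `--maxsubs`) consumes exactly one.

## Clustering

Sorting keys: `fast` = length descending, ties abundance descending then
ordinal; `size` = abundance descending, ties length descending then
ordinal. AGC chooses among *accepted* centroids only (those returned
within the `maxaccepts` budget). The `threads` argument is accepted for
interface compatibility; processing is sequential and thereby trivially
thread-count invariant, which is the semantic contract (parallelism is
an optimization this implementation does not pursue). Center-star MSA
merges member↔centroid alignments on centroid coordinates ("once a gap,
always a gap"); insertions between the same centroid positions are
right-justified. Consensus is abundance-weighted per column; ties prefer
any nucleotide over a gap, then the fixed order A<C<G<T. `--consout`
strips consensus gap columns.

## Dereplication

All comparisons use the normalized sequence (uppercase, U→T); the
representative keeps its original case and first-seen label. Prefix
dereplication processes records shortest-first; within one length class
the order is abundance descending, then label ascending, then input
ordinal — which is precisely what realizes the documented tie-break
chain (shortest candidate → most abundant → lexicographically smaller
label → earliest position) for a sequence that is a prefix of several
candidates. Hash lookups use 64-bit FNV-1a extended one symbol at a
time, so a length-n record's full set of prefix hashes costs O(n);
buckets always verify the full string, so hash collisions can never
merge distinct sequences. Output is sorted by abundance descending, ties
by first occurrence; `--minuniquesize` filters after accumulation.

## Chimera scoring

The candidate-parent search uses the quarter-segment strategy with
identity 0.55, maxaccepts 4, maxrejects 16. The three-way alignment is
built by merging query↔A and query↔B global alignments on query
coordinates. Votes are counted over the whole merged alignment at each
candidate crossover (queries are amplicon-length, so exhaustive
crossover search is affordable): at parent-discriminating columns the
query votes yes for the side's model parent if it matches it, else no;
columns where the parents agree abstain. h = Y / (xn·(N + dn)) with
xn = 8, dn = 1.4, and a crossover is only valid with at least one yes
vote on each side — this is what makes a query identical to one parent
non-chimeric (score 0). Divergence is 100 × (identity of query to the
two-parent model − identity to the best single parent), identities
measured over non-double-gap columns of the merged alignment.
Classification: chimeric iff h ≥ minh (0.28) and divergence ≥ mindiv
(0.8); borderline iff h ≥ minh with smaller divergence. De novo mode
processes records by decreasing abundance and admits as parents only
previously seen non-chimeric records at ≥ abskew (2.0) times the query's
abundance.

## Merging

All overlap placements (any offset with ≥ 1 overlapping column) are
scored; ties prefer the smaller overlap. The winner is then checked, in
order: overlap ≥ `fastq_minovlen` (10), stagger rule, observed
mismatches ≤ `fastq_maxdiffs` (5), merged length in
[`fastq_minmergelen`, `fastq_maxmergelen`]. A placement is staggered
when the reverse-complement start lies left of the forward start; when
allowed, the 3′ overhangs are trimmed and only the overlap consensus is
kept (overhang columns are never scored). Disagreeing columns keep the
higher-quality base, ties keeping the forward base. Posterior error
probabilities: agreement p = (p₁p₂/3)/(1 − p₁ − p₂ + 4p₁p₂/3);
disagreement (p₁ ≤ p₂ after swapping) p = p₁(1 − p₂/3)/(p₁ + p₂ −
4p₁p₂/3); reported as round(−10·log₁₀ p) capped at `fastq_qmaxout`
(41). The "agreement never lowers quality" guarantee holds for q ≥ 2
(the instrument floor); at q ∈ {0, 1} the formulas degenerate (a p = 1
base carries no information) and no such guarantee is claimed. Per-
quality score and probability terms are precomputed as 94×94 tables.

## Masking

DUST with window 64, step 32, level 20: within each window every
subinterval of triplets is scored as Σ c(c−1)/2 over triplet counts
divided by (triplets − 1), the best-scoring subinterval is masked when
10·score > level, and overlapping spans merge. Triplets containing
non-ACGT symbols are skipped. Soft masking lowercases (lossless; word
extraction skips lowercase when the mask mode is `soft`), `--hardmask`
writes N. Search, clustering and chimera commands dust-mask query and
database by default (`--qmask`/`--dbmask` ∈ {none, dust, soft}).

## FASTQ processing

Offset detection: a quality character below code 59 forces Phred+33; a
code of 75 or above with none below 64 indicates Phred+64; a range
confined to [59, 75) is valid under both encodings and is reported as
ambiguous (guessed 33, both interpretations listed). Filtering applies,
in a fixed order: strip left/right → truncate at the first base below
`truncqual` → truncate to `trunclen` (discarding shorter reads) →
length window → N count → expected errors, computed on the read as
truncated. The stats/eestats column layouts (per-position quality
quartiles; EE quartiles per truncation length) are this package's own
documented formats.

## Randomness and subsampling

All seeded randomness uses numpy's PCG64, a named, platform-stable
generator, so `--randseed` reproduces byte-identical output everywhere.
Abundance-aware subsampling draws the multivariate hypergeometric
marginal sequentially per amplicon (remaining-pool hypergeometric
draws), equivalent in distribution to rereplicating, uniformly
subsampling reads, and dereplicating — without materialising the read
multiset. `--sample_pct` converts to a unit count by rounding half up.

## Synthetic data: what it shows and what it does not

The fixture generators produce clustered families (independent random
templates ≈ 75% mutually divergent; members with a bounded substitution
count so family separability at 97% holds by construction, and the exact
template as the most abundant record, as in real amplicon abundance
distributions), labelled two-parent chimeras (parent identity 85–97%,
breakpoint near the middle, parents ≥ 2× the chimera's abundance), and
read pairs with an exact known overlap under a constant-quality model
with optional linear 3′ decay and planted errors. Problem sizes in the
test suite (hundreds of alignment pairs, 100-sequence databases, 10,000
read pairs and subsampling trials) were chosen as the smallest scales at
which the statistical assertions have comfortable margins.

Passing these tests demonstrates algorithmic correctness — oracle
equivalence, conservation laws, exact distributional behaviour — on
idealized inputs. It does not demonstrate accuracy on real platform
error profiles (no homopolymer indel bias, no quality miscalibration,
no length heterogeneity within a family), nor performance at
million-read scale.

## Known limitations

- Single-threaded; `--threads` is accepted for compatibility only.
- bzip2 input is not supported (gzip is); SAM output, UDB databases,
  local alignment and amino-acid alphabets are out of scope.
- The uc/blast6 writers cover the common interoperability columns;
  E-values are not defined for global alignment and are written as
  placeholders in blast6 output.
- Reverse-strand dereplication (merging a read with its reverse
  complement) is not performed.
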