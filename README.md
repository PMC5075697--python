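# amplikit

Amplicon sequence processing for metagenomics: heuristic global-alignment
search, greedy centroid (OTU) clustering, dereplication, chimera
detection, low-complexity masking, paired-end read merging, FASTQ
utilities and abundance-aware subsampling — as a Python library and a
single `amplikit` command following the USEARCH-v7 command/option
vocabulary, so existing pipelines can be pointed at it.

## Who this is for

Targeted metagenomics studies (16S rRNA, ITS, COI markers) produce
millions of short amplicon reads that must be merged, quality-filtered,
dereplicated, clustered into OTUs and screened for PCR chimeras before
any ecological interpretation. `amplikit` implements that toolchain as
plain, testable Python: every step is an ordinary function over
`SequenceRecord` objects, and every heuristic (word-count candidate
shortlisting, accept/reject budgets, greedy cluster assignment) is
explicit and deterministic.

## The core methods

**Search.** A query of length *n* contains at most *n* − *k* + 1 distinct
words (*k*-mers, *k* = 8 by default). Candidate database sequences are
ranked by the number of words shared with the query (each distinct word
counted once), shared-word count descending, length ascending. Candidates
are aligned in that order with an optimal global affine-gap aligner
(match +2, mismatch −4, interior gap open 20 / extend 2, terminal gap
open 2 / extend 1) and accepted when identity ≥ the `--id` threshold;
the scan stops after `--maxaccepts` acceptances (1) or `--maxrejects`
rejections (32). When the length product of a pair exceeds 25,000,000
(two 5,000 bp sequences), alignment switches to a divide-and-conquer
variant using memory linear in the sequence length, with the identical
optimal score. Five identity definitions (`--iddef 0..4`) convert the
alignment's column counts into a fraction.

**Clustering.** Greedy centroid clustering at a similarity threshold
*t*: sequences are processed in the user's order (`--cluster_smallmem`),
by decreasing length (`--cluster_fast`) or decreasing abundance
(`--cluster_size`); each query joins the accepted centroid of highest
identity (DGC) or — with `--sizeorder` — the most abundant accepted
centroid (AGC), otherwise it founds a new cluster. Per cluster, a
center-star multiple alignment, consensus and profile are available.

**Dereplication.** Full-length dereplication collapses identical
normalized sequences (upper case, U→T) via hash lookup with full-string
verification; prefix dereplication additionally absorbs sequences that
are prefixes of longer ones, processing shortest-first with the
tie-break chain *shortest candidate → most abundant → smaller label →
earliest position*, using incremental 64-bit FNV-1a hashes so all
prefixes of a read are hashed in linear total time. `--rereplicate`
expands `;size=N;` annotations back into individual reads.

**Chimera detection** (`--uchime_denovo`, `--uchime_ref`). Candidate
parents are found by searching each quarter of the query (identity 0.55,
maxaccepts 4, maxrejects 16). For each parent pair a three-way alignment
on query coordinates is scored: at columns where the parents differ the
query votes for the parent it matches, and

    h = Y / (xn · (N + dn))        (xn = 8, dn = 1.4)

is maximized over crossover positions, requiring support on both sides.
A query is chimeric when h ≥ 0.28 (`--minh`) and the two-parent model
beats the best single parent by ≥ 0.8 percentage points (`--mindiv`);
high-scoring queries below that divergence are reported as borderline.

**Merging** (`--fastq_mergepairs`). The reverse read is
reverse-complemented and slid along the forward read; each overlap
column contributes a quality-weighted match (+4 at perfect quality) or
mismatch (−5) score under uniform 0.25 base frequencies. The best
overlap must be ≥ 10 columns with ≤ 5 observed mismatches; staggered
placements are rejected unless `--fastq_allowmergestagger`. Overlap
columns receive posterior Phred scores (agreement sharpens, capped at
41; disagreement keeps the better base with reduced confidence).

**Masking, filtering, subsampling.** DUST low-complexity masking
(64-base windows, triplet score Σc(c−1)/2 normalized per triplet,
threshold level 20) is applied as soft masking before word extraction in
search, clustering and chimera detection. `--fastq_filter` truncates and
filters on length, Ns and expected errors EE = Σ 10^(−q/10);
`--fastx_subsample` draws reads without replacement so each amplicon's
output abundance is exactly multivariate-hypergeometric, with a seedable
(`--randseed`) platform-stable PCG64 generator.

## Worked example

Cluster three synthetic amplicon families (15 reads, 300 bp) at 97%:

```sh
python - <<'EOF'
from amplikit import fixtures, seqio
records, _ = fixtures.make_families(seed=11, n_families=3, members_per_family=5)
open("families.fa", "wb").write(seqio.write_fasta(records, width=0, sizeout=True))
EOF
amplikit --cluster_fast families.fa --id 0.97 --sizein --sizeout \
         --centroids centroids.fa --uc clusters.uc
```

prints

```
3 clusters from 15 sequences at id 0.97
```

and `clusters.uc` starts

```
S	0	300	*	*	*	*	*	fam2_m0	*
H	0	300	98.3	+	*	*	300M	fam2_m2	fam2_m0
```

an `S` (seed) record for the first centroid — the longest, here the
exact family-2 template — followed by `H` (hit) records: member
`fam2_m2` joined cluster 0 at 98.3% identity over a 300-column gapless
alignment (`300M`). `centroids.fa` holds one representative per family
with the family's total read count in its `;size=` annotation
(`>fam2_m0;size=214;`).

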