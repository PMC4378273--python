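# Methods

## Scope and data model

The package analyses whole-genome bisulfite sequencing from the
post-alignment contract onward. Its unit of evidence is a *read-stack
entry*: one observed base at one strand-specific cytosine of one read, with
its phred quality, the read's mapping start, and a read identifier. Read
alignment itself (and its mismatch limits) is an upstream input assumption,
not re-checked here. Coordinates are 0-based half-open internally; GFF3 is
emitted and parsed as 1-based inclusive at the IO border only. A CpG
dinucleotide contributes two sites, one per strand, never merged, because
depth and mC counts are per strand-specific cytosine. Context (CpG/CHG/CHH,
H = A, T or C) is read from the two bases 3' of the cytosine on its own
strand; sites within two bases of a contig edge fall back to CHH and carry
`context_complete = False` so they can be excluded.

## Filtering

Bases with phred quality < 30 are discarded. Reads sharing a mapping
position (chromosome, read start, strand) are treated as PCR duplicates and
exactly one read per position is retained — the read whose best surviving
base quality is highest, ties broken by the smallest read identifier — and
all of that read's bases are kept. Retaining a whole read rather than a
single base keeps the filter biologically meaningful for reads that span
several cytosines while staying deterministic; for single-site reads it
reduces to keeping one entry per position. The filter is idempotent.
Pileup then counts C and T observations per site (other bases are ignored
and do not add depth), rejects entries that do not sit on a reference
cytosine of the claimed strand (rejections are counted and logged), and
drops sites with no surviving C/T evidence rather than emitting zero rows,
since every downstream denominator is defined over covered sites.

## Error rate and methylcytosine calling

The library error rate *e* — bisulfite non-conversion plus T→C sequencing
error — is the total C count divided by the total depth over cytosines of
the unmethylated spike-in contig. Zero spike-in depth is a hard error,
never a silent zero. Under the null (unmethylated site), the C count at
depth *n* is Binomial(*n*, *e*); the site p-value is the exact upper tail
P(X ≥ c) (scipy's survival function; no mid-p correction, so the discrete
test is conservative). Every covered site (≥ 1 read) is tested;
Benjamini–Hochberg adjustment is applied per library across all contexts
jointly, and a site is called methylated when q < α with α = 0.01. The
≥ 2X coverage rule applies only to summary denominators, not to calling.

With *e* ≈ 0.004 and depth ≈ 12, BH at 1% typically admits sites with
c ≥ 3 (p ≈ 1e-5) and sits near the boundary for c = 2 (p ≈ 1e-3), so the
realized false-discovery fraction on simulations with 10% true signal is a
few tenths of a percent — controlled, and conservative as FDR theory
predicts under a 90% null fraction.

## Levels, regions and elements

Site level = c/depth, eligible for level analyses only at depth ≥ 5.
Region level is the *unweighted* mean of eligible CpG site levels
intersecting the interval (strand-agnostic); it is undefined (NaN), not
zero, when no eligible CpG falls inside, but the region is still
classifiable: any region holding ≥ 2 called mCGs — regardless of those
sites' 5X eligibility — is "methylated". Region sums use exactly-rounded
summation (`math.fsum`) so a region's level is bit-identical to the plain
mean of its member sites in any order. Gene bodies span TSS to TTS
including introns and UTRs; gene CpG coverage fraction is (gene CpGs at
depth ≥ 2) / (all gene CpGs), and gene-level analyses keep genes at ≥ 70%.

For the per-element summary each eligible CpG is assigned to exactly one
category by precedence: CDS > UTR > intron > ncRNA (tRNA/snRNA/rRNA) >
repeat > 2-kb flank > other, where "other" is all sequence claimed by
nothing else. Genic assignment wins first because the reporting is
gene-centric; the precedence is logged when annotations overlap. The mCG
density track counts called mCGs (both strands) per 1-kb non-overlapping
window divided by the window length, the final partial window by its actual
length, so density × length conserves the total count.

## Profiles, associations, age and enrichment

RPKM = count × 10⁹ / (gene length × mapped reads); optional externally
supplied scale factors are applied as divisors (multiplying the output by
the factors restores the unscaled values), and no further scaling
normalization is performed. Expression ranks: silent genes (RPKM = 0) form
rank 0; expressed genes are sorted by (RPKM, gene id) — the id breaks ties
deterministically — and cut into K contiguous, equal-as-possible bins
(default K = 10; 20 is used for finer summaries). Metagene profiles align
genes at TSS or TTS, flip minus-strand genes so bins run 5'→3' (the flip is
an involution), and pool all eligible CpG site levels from all genes of a
rank into 100-bp bins spanning a 2-kb flank and 2 kb of gene body at each
anchor; genes shorter than the body window contribute only the bins they
cover. Pooling across genes (rather than averaging per-gene means) is
robust to genes with few covered CpGs. Associations use Spearman
correlations (level vs length, level vs RPKM with and without the top 20%
expressed genes, level vs repeat divergence) and one-sided Wilcoxon
rank-sum comparisons (methylated genes longer; methylated repeats less
diverged); degenerate inputs (constant levels) report NaN rather than a
number.

Gene age: species map to the ten nested nodes of the focal lineage
(cellular organisms, Eukaryota, Opisthokonta, Metazoa, Eumetazoa,
Bilateria, Protostomia, Lophotrochozoa, Mollusca, Bivalvia); a gene's
phylostratum is the minimum node over its homology hits, self-hits ignored,
unmappable species excluded with a logged report, and no informative hit
places the gene in the youngest stratum. Adding a hit can only keep or
lower the stratum. Per-stratum methylation is summarized by median and
quartiles over genes passing the coverage rule. GO enrichment builds, per
term, the 2×2 table of stratum vs non-stratum background genes with vs
without the term; the significance flag uses the one-sided Fisher exact
q-value (BH across the stratum's terms, q < 0.05) because Fisher is exact
on small tables, while the χ² p-value is reported alongside.

## The synthetic generator

`simulate_genome` lays out non-overlapping genes (exon/intron/UTR
structure), eight repeat classes (SINE, LINE, LTR, DNA, helitron,
satellite, simple, tandem) carrying divergence rates uniform on [0, 0.5],
a few ncRNAs, and an unmethylated spike-in contig (≥ 200 cytosines
enforced), on uniform-random sequence. Intergenic gaps are drawn uniformly
with a mean set to 60% of the free space per feature, so any feature set
that fits the genome places successfully; an infeasible request raises a
sizing error naming the constraint. Defaults — two 200-kb chromosomes, 80
genes, 6 repeats per class, a 20-kb spike-in — give ~220,000
strand-specific cytosines, large enough for every recovery analysis while
a full simulate-and-analyse cycle stays under ten seconds.

`simulate_methylome` assigns each cytosine a true level. Gene bodies get
*mosaic* methylation: each CpG is methylated (level uniform on [0.8, 1.0])
with a per-gene density equal to the average of a rank component (unimodal
in expression rank: near zero for silent genes, maximal around ranks 7–8,
dipping in the top decile, echoing the observation that moderately
expressed genes are the most methylated) and an age component peaking
sharply at phylostratum 2 and declining toward lineage-specific genes. The
equal-weight additive combination is deliberate: with ~8 genes per stratum
a multiplicative age effect is swamped by the 30-fold rank spread, whereas
the additive design keeps both marginal gradients recoverable at this
scale. Repeat CpG density decays exponentially with divergence
(0.70·e^(−6d)), background CpGs are methylated at density 0.02, and enough
non-CpG sites are methylated to make the CpG share of methylation exactly
the configured fraction (default 99.5%; 1.0 means none). Expression is
lognormal with a 15% silent fraction; phylostrata are cycled over shuffled
genes so every stratum is populated; homology hit tables are generated
consistently with the true strata (one hit at the true node plus optional
younger hits), so the minimum-node rule recovers the truth exactly.

`simulate_read_stacks` places 90-bp reads per strand at the requested mean
depth (default 12 per strand, the depth of a typical wild-sample library),
each read observing C at a cytosine of true level *m* with probability
m + (1 − m)·e (default e = 0.004). It injects a 2% fraction of duplicated
read starts, 5% sub-threshold base qualities and 0.2% non-C/T bases so the
filters are exercised. All three generator stages are deterministic under a
seed.

What the generator does *not* emulate: sequence composition bias (CpG
depletion), per-position quality decay along reads, mapping ambiguity and
polymorphism-driven coverage loss, correlated methylation of neighbouring
CpGs, partially methylated domains, and hemimethylation asymmetry between
strands. Passing recovery tests therefore demonstrates correctness of the
statistics under the stated sampling model, not robustness to real-data
artefacts upstream of the read stack. One consequence of desk scale: with
~200 CpGs per simulated gene, almost every gene exceeds the 2-mCG
"methylated" threshold, so the methylated/unmethylated gene split is far
more lopsided than in real genomes; the repeat split is more balanced and
is the one used to exercise the group comparisons.

## Numerical and degenerate-input choices

Binomial tails come from scipy's exact survival function; BH from
statsmodels (`fdr_bh`), checked in tests against an independent
sort/cummin construction at 1e-12. Spearman, Wilcoxon (Mann–Whitney),
Fisher exact and χ² come from scipy; Fisher is checked against exhaustive
hypergeometric tail summation. Region sums use `fsum` (see above).
Sorting everywhere uses stable mergesort with explicit tie-break keys
(read id, gene id) so reruns are byte-identical. Zero-depth sites, empty
site lists, zero spike-in coverage, α outside (0, 1), negative thresholds
and malformed input lines are hard errors naming the offending value or
line; empty strata, kinds with no assigned CpG, and undefined correlations
are omitted or reported as NaN with a log note, never silently zeroed.

## Problem sizes used in the test and acceptance runs

The FDR benchmark simulates ten replicates of one featureless 200-kb
chromosome (~100,000 cytosines each, 10% methylated at level 0.8) plus a
20-kb spike-in, at ~12 reads per strand — about 2.4 million stack entries
per replicate — and pools calls over replicates. Structure-recovery checks
run the generator's default genome once. Oracle checks use the full
(c ≤ n ≤ 30) binomial grid, 1,000 random p-vectors for BH, 500 random
regions, 1,000 random hit tables and 200 null resamples for enrichment
calibration. These sizes keep a full test run within a few minutes on one
CPU while leaving every Monte-Carlo margin wide.
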