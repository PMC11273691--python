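# Methods

This note records the models, conventions and design choices behind
`peakflow`, in the spirit of a statistical-software methods appendix. It
describes what the code computes and why; every number quoted here is
recomputed by the test suite or by `scripts/acceptance.py`.

## Coordinate conventions

All intervals inside the package are 0-based half-open `[start, end)` —
the BED/narrowPeak convention. GFF3 and GTF are 1-based closed on disk;
conversion (`start − 1` on read, `start + 1` on write) happens exactly
once, at the parse/write boundary in `genomic_io`, and nowhere else.
Round-trip identity (GFF3 → internal → GFF3, GTF write → read) is
enforced by tests.

A gene's TSS is its strand-dependent 5′ end: `interval.start` on `+`,
`interval.end − 1` on `−`. Unstranded (`.`) genes are treated as
plus-stranded for TSS purposes, with a logged warning — a deterministic
rule is preferable to dropping the gene. Exon structure is collapsed to
the gene level as the union of all transcripts' exon records (identical
records deduplicated, overlapping records kept): peaks are annotated per
gene, not per transcript.

Chromosome-name style mismatches (`chr1` vs `1`) between annotation and
peak files are a known silent-failure mode of interval intersection;
the parser logs a warning when an annotation mixes styles, and empty
overlap results should prompt that check first.

## Peak classification

Each peak is represented by a single anchor base: the summit
(`start + summit_offset`) when the peak caller recorded one, else the
floored midpoint. Anchor-point classification, rather than
whole-interval overlap, avoids having to define partial-overlap
semantics and matches summit-centric ATAC/ChIP practice.

The promoter of a gene is the closed symmetric window of half-width L
around the TSS, stored half-open as `[max(0, tss − L), tss + L + 1)`.
L is the `promoter_length` parameter (bp); the CLI default is 1000,
a conventional promoter half-width for mammalian annotation, and the
synthetic fixtures use 300 to keep their genome compact.

Categories are assigned with fixed precedence

    promoter > exon > intron (gene body) > intergenic.

Promoter is deliberately tested **before** gene-body containment:
the ±L window extends upstream of the gene body, so a gene-first rule
would misclassify upstream promoter hits as intergenic, contradicting
the symmetric-window definition itself. When several genes match at the
winning level, the gene with the smallest |anchor − TSS| is reported,
ties broken by lexicographic gene id — nearest-TSS is only a tie-break
within the winning category, never the primary rule. One gene is
reported per peak; `classify_peak` exposes the index so callers needing
all overlapping genes can query it directly.

Point queries run against interval trees (one per chromosome per
category). Correctness is established by equivalence with an exhaustive
per-gene linear scan on random annotations of up to 50 (possibly
overlapping) genes × 1000 random peaks × 20 replicates, and by exact
recovery of the synthetic generator's planted truth tables.

## Consensus peaks and matrices

Merging is single-linkage over the ≥ 1 bp overlap graph of all peaks
from all input files: consensus intervals are the connected components,
spanning `[min start, max end)`. This is implemented as a sorted sweep,
is independent of input order, and admits a per-base oracle: consensus
coverage must equal the boolean OR of per-sample coverage, intervals
must be disjoint and sorted, and every source peak must land in exactly
one consensus interval. Identifiers `consensus_<k>` follow
(chrom, start) sort rank, so re-runs are reproducible. Whether
replicates should be merged before or across samples is left to the
caller: all provided files are merged in one pass and per-file
provenance is recorded.

Fragment counting uses union-mode semantics: a fragment increments a
consensus interval only when it overlaps exactly one (≥ 1 bp); fragments
hitting zero or several intervals are discarded and tallied in the log.
This mirrors the default of the standard htseq-style counters and keeps
column sums ≤ fragment counts, with equality iff nothing was ambiguous.

The q-value matrix stores, per (consensus interval, sample), the maximum
−log10 q-value over that sample's contributing peaks — the strongest
evidence, rather than a mean that would dilute a confident sub-peak —
and 0 where the sample contributed no peak (absence of a call is no
evidence, not missing data). narrowPeak's `-1` missing-q sentinel is
stored as 0 with a warning; any other negative q is a format error.

Normalisation is median-of-ratios size factors: for features with
positive counts in every sample, sⱼ = medianᵢ(cᵢⱼ / gᵢ) with gᵢ the
geometric mean of feature i across samples, followed by
log2(c/s + 1). The full variance-stabilising transform of the external
DE engine (dispersion-trend fitting) is intentionally **not**
re-implemented: downstream clustering only needs variance-comparable
inputs, and the matrix `kind` field records exactly which transform was
applied. The log2(x + 1) form maps zero counts to zero and is exactly
invertible given the stored factors, which the tests exploit.

## Clustering with automatic k

Distances between feature profiles are euclidean or correlation
(1 − Pearson r) over the sample dimensions; q-value matrices are used on
their −log10 scale directly. Constant rows have no defined correlation;
their distance is set to 0 for identical rows and 1 otherwise, with a
warning — a documented convention beats NaN propagation.

The silhouette of point i is s(i) = (b − a)/max(a, b), with a(i) the
mean distance to the other members of its own cluster, b(i) the smallest
mean distance to another cluster, s = 0 for singleton clusters and for
the 0/0 case of coincident points (the standard conventions). The
implementation is vectorised over a precomputed distance matrix and is
checked against both a literal triple-loop evaluation of the formula
(all random instances n ≤ 30) and scikit-learn's `silhouette_samples`;
the 4-point line {0, 1, 10, 11} in clusters {0,1}/{10,11} evaluates to
(9.5/10.5 + 8.5/9.5)/2 ≈ 0.8997 by hand, which the tests pin.

`select_k` clusters at every k in a scan range (default
[2, min(15, n − 1)]) and keeps the silhouette argmax, ties to the
smaller k (parsimony). K-means is Lloyd's algorithm with k-means++
seeding, n_init = 10 restarts and max_iter = 300 (scikit-learn);
agglomerative clustering cuts a scipy linkage tree (average, complete,
or ward — ward is refused for non-euclidean distances since it assumes
squared-euclidean geometry). Both are deterministic given the seed /
the distance matrix; agglomerative merges are verified against a
literal greedy-merge re-implementation on n ≤ 7.

t-SNE (fixed seed, PCA initialisation) is presentation-only: cluster
labels always come from the full-dimensional data, and the embedding is
emitted as plot data. Heatmap rows are ordered by cluster id, then by
within-cluster mean signal descending (stable sort), with boundaries at
cumulative cluster sizes.

## DE plot layer

The differential test itself is external; its result table
(feature_id, baseMean, log2FoldChange, padj) is consumed as-is. Volcano
labels use inclusive cutoffs (up iff log2FC ≥ L and padj ≤ α; down
symmetric; else ns); features whose padj is missing — the external
engine's independent-filtering artifacts — are kept and labelled ns
rather than dropped. MA points use A = log10(baseMean + 1) (bounded at
0 for silent features) and M = log2FC, with the significance flag
defined as the volcano rule's non-ns outcome so the two plots can never
disagree. Sample PCA mean-centres samples-as-observations over
features-as-variables and reports the explained-variance spectrum.

## Synthetic fixtures

The generators are pure functions of their seed (fixed seed ⇒ identical
bytes) and are first-class, tested code.

*Annotation*: `n_genes` non-overlapping genes of 3–6 kb with 2–5
disjoint exons each, random strands, consecutive genes separated by at
least `2 × promoter_length + 200` bp. That spacing guarantees no
promoter window reaches another gene's body and every inter-gene gap
contains a provably intergenic corridor, which is what makes the planted
peak categories unambiguous.

*Labelled peaks*: category regions are built by explicit interval
arithmetic (exon minus promoter window, body minus exons minus window,
gap centres more than L + 50 bp from either neighbour), then anchors are
drawn inside them and peaks of 120–240 bp placed with the summit on the
anchor. A requested category with no eligible region (e.g. introns under
a promoter window wider than every gene) is a validation error, not a
silent shortfall.

*Count matrices*: features are drawn around `planted_k` centroids in
log2 space (base level 7 ≈ 128 counts) with N(0, noise_sd²) noise,
exponentiated, scaled per sample and rounded. Centroids sit on the
vertices of a regular simplex scaled so the minimum pairwise spacing is
exactly `separation × noise_sd`, then randomly coordinate-permuted and
sign-flipped per seed (both distance-preserving). The simplex keeps
every centroid coordinate within ~0.9× the spacing of the base level,
so the planted geometry survives the exponentiate-round-log2 pipeline;
unbounded random centroid draws can sink whole clusters below zero
counts, where clipping erases the separation the generator promised.
Two centroid modes exist: `profile` (default) gives clusters distinct
cross-sample profiles and is the clustering fixture; `abundance` makes
clusters differ only in overall level, identically in every sample, so
the only systematic between-sample difference is the applied library
scaling — the mostly-undisturbed regime the median-of-ratios estimator
assumes. The size-factor recovery checks use abundance mode with
planted_k = 2, separation = 4, noise_sd = 0.5 and 1000 features per
cluster (the estimator's median error shrinks like noise/√n_features;
at these sizes recovered ratios are within ~3%); profile mode
deliberately violates the mostly-non-differential assumption — every
feature shifts — and measurably biases size factors, a property of
composition-shifted data rather than of the estimator.

What the fixtures do **not** emulate: negative-binomial dispersion,
fragment-length distributions, overlapping genes, chromosome-scale gene
density, or missing/duplicated annotation records. Passing tests
therefore demonstrate the correctness of the interval logic, the
normalisation arithmetic and the selection machinery under clean planted
conditions — not robustness to the full messiness of real libraries.

## Execution model

The initialization file is INI-style, one section per stage plus
`[project]`, each stage carrying `enabled` and its parameters; unknown
sections/keys, duplicates and type mismatches are rejected with the
valid alternatives listed, and an empty file is a valid all-disabled
configuration. Sample discovery groups FASTQ-named files by the maximal
prefix before the first recognized token — case-insensitive
`rep<digits>` for replicates, `_R1`/`_R2` for mates — and treats an
unmatched mate as an error naming the orphan file. The project layout is
`project_dir/<sample>/<module>/`, created idempotently, with a
`manifest.json` (config hash, seed, package version, sample sheet)
sufficient to re-execute the run identically.

## Verification scale

The acceptance script and the heavier tests run at desk scale on one
CPU: 20 random annotations × 1000 peaks for the classification oracle,
10 × 500 fragments for the counting oracle, 100 kb per-base coverage
arrays, 50 silhouette instances at n ≤ 30, and 2 algorithms × 4 planted
k × 10 seeds for cluster-number recovery (k scanned over [2, 8], which
brackets the planted range). These sizes were chosen so the full
verification completes in well under a minute while keeping every check
statistically meaningful.

## Known limitations

- Anchor-point classification ignores peak width; a peak straddling a
  promoter boundary is classified entirely by its summit.
- Single-linkage merging can chain touching peaks into long consensus
  intervals in dense regions; no re-splitting is attempted.
- Median-of-ratios factors assume most features are undisturbed between
  samples; global composition shifts bias them (demonstrated by the
  profile-mode fixture).
- Correlation distance on near-constant rows is dominated by the
  constant-row convention.
- t-SNE coordinates are seed-reproducible but not comparable across
  runs with different seeds or perplexities.
- BAM/SAM input is out of scope; fragments must arrive as BED.
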