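"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle re-derives an expected result by the most literal method
available (linear scans, per-base coverage arrays, all-pairs loops,
triple-loop formula evaluation, greedy merging) and never calls the code
path it checks.
"""

from __future__ import annotations

import numpy as np

from peakflow.genomic_io import Gene, GeneAnnotation, GenomicInterval, Peak, PeakSet


# ---------------------------------------------------------------------------
# peak classification: exhaustive linear scan over every gene
# ---------------------------------------------------------------------------

def brute_force_classify(
    peak: Peak, annotation: GeneAnnotation, promoter_length: int
) -> tuple[str, str]:
    """Classify a peak by scanning every gene linearly, per the same rules:

    anchor = summit or midpoint; precedence promoter > exon > intron;
    among genes matching at the winning level, nearest TSS wins, ties by
    lexicographic gene_id; otherwise intergenic.
    """
    anchor = peak.anchor
    chrom = peak.interval.chrom
    L = promoter_length
    for category in ("promoter", "exon", "intron"):
        hits = []
        for gene in annotation:
            if gene.interval.chrom != chrom:
                continue
            if category == "promoter":
                inside = max(0, gene.tss - L) <= anchor <= gene.tss + L
            elif category == "exon":
                inside = any(e.start <= anchor < e.end for e in gene.exons)
            else:
                inside = gene.interval.start <= anchor < gene.interval.end
            if inside:
                hits.append(gene)
        if hits:
            best = min(hits, key=lambda g: (abs(anchor - g.tss), g.gene_id))
            return category, best.gene_id
    return "intergenic", ""


def random_annotation(
    rng: np.random.Generator,
    n_genes: int = 30,
    chrom_length: int = 100_000,
    n_chroms: int = 2,
) -> GeneAnnotation:
    """Random genes that may overlap each other (the hard case for the index)."""
    genes = {}
    for i in range(n_genes):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        start = int(rng.integers(0, chrom_length - 5000))
        length = int(rng.integers(500, 5000))
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 5))
        exons = []
        for _ in range(n_exons):
            e_start = start + int(rng.integers(0, max(1, length - 100)))
            e_len = int(rng.integers(50, 200))
            exons.append(
                GenomicInterval(chrom, e_start, min(e_start + e_len, start + length), strand)
            )
        gene_id = f"g{i:03d}"
        genes[gene_id] = Gene(
            gene_id, GenomicInterval(chrom, start, start + length, strand), tuple(exons)
        )
    return GeneAnnotation(genes=genes)


def random_peaks(
    rng: np.random.Generator,
    n_peaks: int,
    chrom_length: int = 100_000,
    n_chroms: int = 2,
) -> PeakSet:
    """Random peaks, some without a recorded summit."""
    peaks = []
    for i in range(n_peaks):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        start = int(rng.integers(0, chrom_length - 1000))
        length = int(rng.integers(100, 900))
        summit = int(rng.integers(0, length)) if rng.random() < 0.8 else -1
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, start, start + length),
                name=f"p{i:04d}",
                neg_log10_q=float(rng.uniform(0.5, 10)),
                summit_offset=summit,
            )
        )
    return PeakSet(sample_id="oracle", peaks=peaks)


# ---------------------------------------------------------------------------
# consensus merging: per-base coverage arrays
# ---------------------------------------------------------------------------

def coverage_array(
    intervals: list[GenomicInterval], chrom: str, length: int
) -> np.ndarray:
    cov = np.zeros(length, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            cov[iv.start : iv.end] = True
    return cov


# ---------------------------------------------------------------------------
# union-mode counting: quadratic all-pairs
# ---------------------------------------------------------------------------

def brute_force_counts(
    fragments: list[GenomicInterval], consensus_intervals: list[GenomicInterval]
) -> np.ndarray:
    counts = np.zeros(len(consensus_intervals), dtype=int)
    for frag in fragments:
        hits = [
            i for i, iv in enumerate(consensus_intervals) if frag.overlaps(iv)
        ]
        if len(hits) == 1:
            counts[hits[0]] += 1
    return counts


# ---------------------------------------------------------------------------
# silhouette: naive triple loop
# ---------------------------------------------------------------------------

def brute_force_silhouette(labels: np.ndarray, D: np.ndarray) -> tuple[float, np.ndarray]:
    n = len(labels)
    ids = sorted(set(labels.tolist()))
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        own_members = [j for j in range(n) if labels[j] == own and j != i]
        if not own_members:
            s[i] = 0.0  # singleton
            continue
        a = sum(D[i, j] for j in own_members) / len(own_members)
        b = min(
            sum(D[i, j] for j in range(n) if labels[j] == c)
            / sum(1 for j in range(n) if labels[j] == c)
            for c in ids
            if c != own
        )
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean()), s


# ---------------------------------------------------------------------------
# agglomerative clustering: literal greedy merging (tiny n)
# ---------------------------------------------------------------------------

def greedy_agglomerative(D: np.ndarray, k: int, linkage: str) -> list[set[int]]:
    """Merge the closest cluster pair repeatedly until k clusters remain.

    Inter-cluster distance is the mean (average linkage) or max (complete
    linkage) of the original point distances; ties go to the smallest pair
    index.
    """
    clusters: list[set[int]] = [{i} for i in range(len(D))]
    while len(clusters) > k:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dists = [D[i, j] for i in clusters[a] for j in clusters[b]]
                d = float(np.mean(dists)) if linkage == "average" else float(max(dists))
                if best is None or d < best[0]:
                    best = (d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return clusters


def labels_to_partition(labels: np.ndarray) -> set[frozenset[int]]:
    out: dict[int, set[int]] = {}
    for i, lab in enumerate(labels):
        out.setdefault(int(lab), set()).add(i)
    return {frozenset(v) for v in out.values()}
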