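"""Synthetic annotation, peak, fragment, and matrix fixtures with ground truth.

Every generator is a pure function of its seed, so fixtures are
reproducible byte-for-byte and can be regenerated anywhere without
downloads. The fixtures are deliberately idealised: genes are spaced so
far apart (at least two promoter widths) that every planted peak category
is unambiguous, and count matrices are log-normal perturbations around
planted centroids rather than a realistic negative-binomial read
simulator. They exercise the interval logic, the normalisation arithmetic
and the cluster-number selection — not read-level noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist

from .consensus_matrix import SignalMatrix
from .errors import ValidationError
from .genomic_io import (
    Gene,
    GeneAnnotation,
    GenomicInterval,
    Peak,
    PeakSet,
    write_bed6,
    write_gff3,
)

CHROM = "chr1"
CATEGORIES = ("promoter", "exon", "intron", "intergenic")


@dataclass
class FixtureSpec:
    """Parameters of the synthetic data generators.

    separation is the ratio of between-cluster centroid spacing to the
    within-cluster spread noise_sd (both in log2 count units).
    """

    seed: int = 0
    n_genes: int = 30
    chrom_length: int = 2_000_000
    promoter_length: int = 300
    peaks_per_category: dict[str, int] = field(
        default_factory=lambda: {c: 10 for c in CATEGORIES}
    )
    n_samples: int = 4
    planted_k: int = 3
    separation: float = 10.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.peaks_per_category.values()):
            raise ValidationError("peaks_per_category counts must be >= 0")
        unknown = set(self.peaks_per_category) - set(CATEGORIES)
        if unknown:
            raise ValidationError(f"unknown peak categories {sorted(unknown)}")
        if self.separation <= 0:
            raise ValidationError("separation must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.promoter_length <= 0:
            raise ValidationError("promoter_length must be > 0")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_GENE_LEN = (3000, 6000)   # long enough that exons/introns clear the promoter
_GAP_EXTRA = (0, 1000)


def make_annotation(
    spec: FixtureSpec, path: str | Path | None = None
) -> GeneAnnotation:
    """Place non-overlapping genes with 2-5 exons each on one chromosome.

    Consecutive genes are separated by at least 2 * promoter_length + 200 bp
    so no promoter window of one gene can reach another gene's body and a
    guaranteed-intergenic corridor exists in every gap. Optionally writes
    the annotation as GFF3 (deterministic bytes for a fixed seed).
    """
    rng = np.random.default_rng(spec.seed)
    min_gap = 2 * spec.promoter_length + 200
    genes: dict[str, Gene] = {}
    cursor = min_gap
    for i in range(spec.n_genes):
        length = int(rng.integers(*_GENE_LEN))
        gap = min_gap + int(rng.integers(*_GAP_EXTRA))
        start = cursor
        end = start + length
        if end + min_gap > spec.chrom_length:
            raise ValidationError(
                f"cannot pack {spec.n_genes} genes into chrom_length="
                f"{spec.chrom_length}; ran out of room at gene {i}"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"gene_{i + 1:04d}"
        genes[gene_id] = Gene(
            gene_id=gene_id,
            interval=GenomicInterval(CHROM, start, end, strand),
            exons=tuple(_make_exons(rng, start, end, strand)),
        )
        cursor = end + gap

    ann = GeneAnnotation(genes=genes, source_path=str(path) if path else "<synthetic>")
    if path is not None:
        write_gff3(ann, path)
    return ann


def _make_exons(rng: np.random.Generator, start: int, end: int, strand: str):
    """2-5 disjoint exons inside the gene body, one per equal segment."""
    n_exons = int(rng.integers(2, 6))
    seg = (end - start) // n_exons
    exons = []
    for j in range(n_exons):
        seg_lo = start + j * seg
        offset = int(rng.integers(0, seg // 4))
        length = int(rng.integers(seg // 4, seg // 2))
        exons.append(GenomicInterval(CHROM, seg_lo + offset, seg_lo + offset + length, strand))
    return exons


# ---------------------------------------------------------------------------
# labelled peaks
# ---------------------------------------------------------------------------

def _subtract(region: tuple[int, int], hole: tuple[int, int]) -> list[tuple[int, int]]:
    """region minus hole, as 0, 1 or 2 half-open intervals."""
    lo, hi = region
    hlo, hhi = hole
    out = []
    if hlo > lo:
        out.append((lo, min(hi, hlo)))
    if hhi < hi:
        out.append((max(lo, hhi), hi))
    return [(a, b) for a, b in out if b > a]


def make_labeled_peaks(
    spec: FixtureSpec,
    annotation: GeneAnnotation,
    sample_id: str = "synthetic",
):
    """Plant peaks whose summits provably fall in a requested category.

    Summits are chosen inside regions constructed by interval arithmetic:
    promoter anchors near a TSS; exon anchors on exon bases outside every
    promoter window; intron anchors on gene-body bases on no exon and in no
    promoter window; intergenic anchors in the middle of inter-gene gaps,
    more than one promoter width from either neighbour. Returns the
    (sorted) PeakSet and a truth table of (peak_name, category, gene_id)
    rows in peak-name order.

    Raises a validation error if some requested category has no eligible
    region (e.g. introns under a promoter window wider than every gene).
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed + 1)
    L = spec.promoter_length
    genes = sorted(annotation, key=lambda g: g.interval.start)

    # eligible anchor regions per category
    regions: dict[str, list[tuple[int, int, str]]] = {c: [] for c in CATEGORIES}
    for gene in genes:
        tss = gene.tss
        window = (max(0, tss - L), tss + L + 1)
        regions["promoter"].append((*window, gene.gene_id))
        body = (gene.interval.start, gene.interval.end)
        exon_iv = [(e.start, e.end) for e in gene.exons]
        for lo, hi in exon_iv:
            for piece in _subtract((lo, hi), window):
                regions["exon"].append((*piece, gene.gene_id))
        introns = [body]
        for hole in exon_iv + [window]:
            introns = [p for r in introns for p in _subtract(r, hole)]
        for lo, hi in introns:
            regions["intron"].append((lo, hi, gene.gene_id))
    # gaps between consecutive genes, shrunk by L + 50 on both sides
    bounds = [0] + [g.interval.end for g in genes]
    nexts = [g.interval.start for g in genes] + [spec.chrom_length]
    for lo, hi in zip(bounds, nexts):
        safe = (lo + L + 50, hi - L - 50)
        if safe[1] > safe[0]:
            regions["intergenic"].append((*safe, ""))

    peaks: list[Peak] = []
    truth_rows = []
    counter = 0
    for category in CATEGORIES:
        want = spec.peaks_per_category.get(category, 0)
        eligible = [r for r in regions[category] if r[1] > r[0]]
        if want > 0 and not eligible:
            raise ValidationError(
                f"no eligible region to place {category!r} peaks "
                "(promoter window too wide for this annotation?)"
            )
        for _ in range(want):
            counter += 1
            lo, hi, gene_id = eligible[int(rng.integers(len(eligible)))]
            anchor = int(rng.integers(lo, hi))
            half = int(rng.integers(60, 120))
            start = max(0, anchor - half)
            end = anchor + half
            name = f"peak_{counter:04d}"
            peaks.append(
                Peak(
                    interval=GenomicInterval(CHROM, start, end),
                    name=name,
                    signal=float(np.round(rng.uniform(1, 20), 3)),
                    neg_log10_p=float(np.round(rng.uniform(2, 20), 3)),
                    neg_log10_q=float(np.round(rng.uniform(1, 10), 3)),
                    summit_offset=anchor - start,
                )
            )
            truth_rows.append(
                {"peak_name": name, "category": category, "gene_id": gene_id}
            )
    truth = pd.DataFrame(truth_rows, columns=["peak_name", "category", "gene_id"])
    return PeakSet(sample_id=sample_id, peaks=peaks), truth


# ---------------------------------------------------------------------------
# peak sets for merging, fragments for counting
# ---------------------------------------------------------------------------

def make_random_peakset(
    seed: int, sample_id: str, n_peaks: int = 50, chrom_length: int = 100_000,
    n_chroms: int = 2,
) -> PeakSet:
    """Random (possibly mutually overlapping) peaks for merge/count tests."""
    rng = np.random.default_rng(seed)
    peaks = []
    for i in range(n_peaks):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        start = int(rng.integers(0, chrom_length - 1000))
        length = int(rng.integers(100, 900))
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, start, start + length),
                name=f"{sample_id}_p{i + 1}",
                signal=float(np.round(rng.uniform(1, 30), 3)),
                neg_log10_p=float(np.round(rng.uniform(1, 30), 3)),
                neg_log10_q=float(np.round(rng.uniform(0.5, 15), 3)),
                summit_offset=int(rng.integers(0, length)),
            )
        )
    return PeakSet(sample_id=sample_id, peaks=peaks)


def make_fragments(
    seed: int, n_fragments: int = 500, chrom_length: int = 100_000,
    n_chroms: int = 2, path: str | Path | None = None,
) -> list[GenomicInterval]:
    """Random BED fragments (50-400 bp) for union-mode counting tests."""
    rng = np.random.default_rng(seed)
    frags = []
    for _ in range(n_fragments):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        start = int(rng.integers(0, chrom_length - 500))
        length = int(rng.integers(50, 400))
        frags.append(GenomicInterval(chrom, start, start + length))
    if path is not None:
        write_bed6(((f"frag_{i + 1}", iv) for i, iv in enumerate(frags)), path)
    return frags


# ---------------------------------------------------------------------------
# count matrices with planted clusters
# ---------------------------------------------------------------------------

def _simplex_offsets(k: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """k centroid directions in R^d with equal pairwise distances and
    coordinates bounded by ~0.9x the pairwise distance.

    Equidistant vertices (a regular simplex when k <= d + 1) keep every
    coordinate close to the base expression level, so planted separation
    survives the exponentiate-round-log2 pipeline: unbounded random draws
    can sink whole clusters below zero counts, where clipping erases the
    planted geometry. Coordinates are randomly permuted and sign-flipped
    per seed (both distance-preserving) for variety across seeds.
    """
    if k <= d + 1:
        vertices = np.zeros((k, d))
        for i in range(min(k, d)):
            vertices[i, i] = 1.0
        if k == d + 1:
            # the extra vertex equidistant from all e_i: c * (1, ..., 1)
            c = (1.0 - np.sqrt(d + 1.0)) / d
            vertices[d, :] = c
        vertices -= vertices.mean(axis=0, keepdims=True)
    else:  # more clusters than samples + 1: no regular simplex exists
        vertices = rng.normal(size=(k, d))
        vertices -= vertices.mean(axis=0, keepdims=True)
        if pdist(vertices).min() == 0:
            raise ValidationError("degenerate centroid draw; change the seed")
        vertices /= np.abs(vertices).max()
    perm = rng.permutation(d)
    signs = rng.choice([-1.0, 1.0], size=d)
    return vertices[:, perm] * signs[np.newaxis, :]


def make_count_matrix(
    spec: FixtureSpec,
    features_per_cluster: int = 40,
    sample_scalings: np.ndarray | list[float] | None = None,
    mode: str = "profile",
):
    """Counts around planted_k centroids in log2 sample-space.

    In ``profile`` mode (the clustering fixture) centroids are placed so
    their minimum pairwise distance equals separation * noise_sd (in log2
    units), giving each cluster a distinct cross-sample profile; each
    feature is its centroid plus N(0, noise_sd^2) noise, exponentiated,
    scaled by its sample's library-size factor and rounded to a
    nonnegative integer.

    In ``abundance`` mode (the normalisation fixture) clusters differ only
    in overall expression level, identically in every sample, so the only
    systematic between-sample difference is the applied library-size
    scaling — the mostly-undisturbed regime the median-of-ratios estimator
    assumes. Profile mode deliberately violates that assumption (every
    feature is "differential"), which biases size factors; that is a
    property of composition-shifted data, not of the estimator.

    Returns the raw-count SignalMatrix, the true per-feature labels, and
    the scalings applied.
    """
    if mode not in ("profile", "abundance"):
        raise ValidationError(f"mode must be 'profile' or 'abundance', got {mode!r}")
    if spec.planted_k < 2:
        raise ValidationError("planted_k must be >= 2")
    if spec.n_samples < 2:
        raise ValidationError("n_samples must be >= 2")
    n_features = spec.planted_k * features_per_cluster
    if spec.planted_k > n_features:
        raise ValidationError("planted_k exceeds the number of features")

    rng = np.random.default_rng(spec.seed + 2)
    base = 7.0  # log2 count level around which centroids sit
    if mode == "profile":
        offsets = _simplex_offsets(spec.planted_k, spec.n_samples, rng)
        min_dist = pdist(offsets).min()
        centroids = base + offsets * (spec.separation * spec.noise_sd / min_dist)
    else:
        # per-cluster overall level, identical across samples
        levels = np.arange(spec.planted_k) * spec.separation * spec.noise_sd
        levels = levels - levels.mean()
        centroids = base + np.tile(levels[:, np.newaxis], (1, spec.n_samples))

    labels = np.repeat(np.arange(spec.planted_k), features_per_cluster)
    log2_values = centroids[labels] + rng.normal(
        scale=spec.noise_sd, size=(n_features, spec.n_samples)
    )
    if sample_scalings is None:
        scalings = np.ones(spec.n_samples)
    else:
        scalings = np.asarray(sample_scalings, dtype=float)
        if scalings.shape != (spec.n_samples,):
            raise ValidationError(
                f"sample_scalings must have length {spec.n_samples}"
            )
    counts = np.rint(np.exp2(log2_values) * scalings[np.newaxis, :])
    counts = np.clip(counts, 0, None)
    matrix = SignalMatrix(
        feature_ids=[f"feature_{i + 1}" for i in range(n_features)],
        sample_ids=[f"sample_{j + 1}" for j in range(spec.n_samples)],
        values=counts,
        kind="raw_counts",
    )
    return matrix, labels, scalings
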