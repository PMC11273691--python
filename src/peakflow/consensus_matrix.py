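"""Consensus peak sets and the features x samples signal matrix.

Per-sample narrowPeak calls are merged into a single consensus set: two
peaks join the same consensus interval iff they share at least one base
(single-linkage over the overlap graph), and each consensus interval spans
its component from min start to max end. Consensus ids ``consensus_<k>``
number the intervals by (chrom, start) sort rank, so re-runs on the same
input are reproducible.

Signal matrices over the consensus set carry either integer fragment
counts (union-mode assignment: a fragment must hit exactly one consensus
interval to be counted) or the strongest MACS2 -log10 q-value each sample
contributed. Count matrices are normalised by median-of-ratios size
factors followed by a log2(x + 1) transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ValidationError
from .genomic_io import GenomicInterval, PeakSet, parse_bed6, write_bed6, write_gtf

logger = logging.getLogger(__name__)

MATRIX_KINDS = ("raw_counts", "normalized", "neg_log10_q")


@dataclass(frozen=True)
class ConsensusPeak:
    consensus_id: str
    interval: GenomicInterval
    # sample_id -> names of that sample's source peaks inside this interval
    contributing: dict[str, tuple[str, ...]] = field(default_factory=dict)


@dataclass
class ConsensusPeakSet:
    """Merged, uniquely identified, disjoint consensus intervals."""

    peaks: list[ConsensusPeak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def ids(self) -> list[str]:
        return [p.consensus_id for p in self.peaks]

    def to_bed(self, path: str | Path) -> None:
        write_bed6(((p.consensus_id, p.interval) for p in self.peaks), path)

    def to_gtf(self, path: str | Path) -> None:
        write_gtf([(p.consensus_id, p.interval) for p in self.peaks], path)

    def trees(self) -> dict[str, IntervalTree]:
        """Row-index interval trees keyed by chromosome."""
        trees: dict[str, IntervalTree] = {}
        for row, peak in enumerate(self.peaks):
            trees.setdefault(peak.interval.chrom, IntervalTree())[
                peak.interval.start:peak.interval.end
            ] = row
        return trees


@dataclass
class SignalMatrix:
    """Features x samples numeric matrix with explicit normalisation state."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    kind: str
    size_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in MATRIX_KINDS:
            raise ValidationError(f"kind must be one of {MATRIX_KINDS}, got {self.kind!r}")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("matrix values must be finite")
        if self.kind in ("raw_counts", "neg_log10_q") and np.any(self.values < 0):
            raise ValidationError(f"{self.kind} matrix must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "feature_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str = "raw_counts") -> "SignalMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            feature_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            kind=kind,
        )


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_peaksets(peaksets: Sequence[PeakSet]) -> ConsensusPeakSet:
    """Merge peak sets from all samples into a consensus set.

    Consensus intervals are the connected components of the >= 1 bp overlap
    graph over all input peaks (single linkage); each component spans
    [min start, max end). Provenance records which source peaks of which
    sample fell into each interval.
    """
    if not peaksets:
        raise ValidationError("merge_peaksets requires at least one PeakSet")

    entries: list[tuple[str, int, int, str, str]] = []
    for ps in peaksets:
        for peak in ps:
            entries.append(
                (peak.interval.chrom, peak.interval.start, peak.interval.end,
                 ps.sample_id, peak.name)
            )
    entries.sort()

    merged: list[tuple[str, int, int, dict[str, list[str]]]] = []
    for chrom, start, end, sample, name in entries:
        if merged and merged[-1][0] == chrom and start < merged[-1][2]:
            prev = merged[-1]
            prev[3].setdefault(sample, []).append(name)
            merged[-1] = (chrom, prev[1], max(prev[2], end), prev[3])
        else:
            merged.append((chrom, start, end, {sample: [name]}))

    peaks = [
        ConsensusPeak(
            consensus_id=f"consensus_{k}",
            interval=GenomicInterval(chrom, start, end),
            contributing={s: tuple(names) for s, names in sorted(contrib.items())},
        )
        for k, (chrom, start, end, contrib) in enumerate(merged, start=1)
    ]
    logger.info(
        "merged %d source peaks from %d file(s) into %d consensus intervals",
        len(entries), len(peaksets), len(peaks),
    )
    return ConsensusPeakSet(peaks=peaks)


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def count_fragments(
    fragments: str | Path | Sequence[GenomicInterval],
    consensus: ConsensusPeakSet,
    sample_id: str,
) -> np.ndarray:
    """Count fragments per consensus interval under union-mode assignment.

    A fragment increments exactly one consensus interval iff it overlaps
    exactly one by >= 1 bp; fragments hitting zero or two-plus intervals are
    discarded and tallied in the log. Returns one integer column aligned
    with ``consensus.ids``.
    """
    if isinstance(fragments, (str, Path)):
        fragments = parse_bed6(fragments)
    trees = consensus.trees()
    counts = np.zeros(len(consensus), dtype=int)
    unassigned = ambiguous = 0
    for frag in fragments:
        tree = trees.get(frag.chrom)
        hits = tree.overlap(frag.start, frag.end) if tree is not None else ()
        if len(hits) == 1:
            counts[next(iter(hits)).data] += 1
        elif len(hits) == 0:
            unassigned += 1
        else:
            ambiguous += 1
    logger.info(
        "%s: %d fragments assigned, %d outside all intervals, %d ambiguous",
        sample_id, int(counts.sum()), unassigned, ambiguous,
    )
    return counts


def build_count_matrix(
    fragment_files: dict[str, str | Path], consensus: ConsensusPeakSet
) -> SignalMatrix:
    """Assemble the raw count matrix from per-sample fragment BED files."""
    sample_ids = list(fragment_files)
    cols = [
        count_fragments(fragment_files[s], consensus, s) for s in sample_ids
    ]
    return SignalMatrix(
        feature_ids=consensus.ids,
        sample_ids=sample_ids,
        values=np.column_stack(cols) if cols else np.zeros((len(consensus), 0)),
        kind="raw_counts",
    )


def build_qvalue_matrix(
    peaksets: Sequence[PeakSet], consensus: ConsensusPeakSet
) -> SignalMatrix:
    """Build the -log10 q-value matrix over the consensus set.

    Each cell holds the maximum -log10 q-value over the sample's source
    peaks that fall inside the consensus interval, or 0 when the sample
    contributed none — absence of a call is treated as no evidence.
    """
    sample_ids = [ps.sample_id for ps in peaksets]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError("duplicate sample_id across peak sets")

    trees = consensus.trees()
    values = np.zeros((len(consensus), len(sample_ids)))
    for j, ps in enumerate(peaksets):
        for peak in ps:
            tree = trees.get(peak.interval.chrom)
            hits = (
                tree.overlap(peak.interval.start, peak.interval.end)
                if tree is not None else ()
            )
            if len(hits) != 1:
                raise ValidationError(
                    f"source peak {peak.name} maps to {len(hits)} consensus "
                    "intervals; the consensus set was not built from these peaks"
                )
            row = next(iter(hits)).data
            values[row, j] = max(values[row, j], peak.neg_log10_q)
    return SignalMatrix(
        feature_ids=consensus.ids, sample_ids=sample_ids, values=values,
        kind="neg_log10_q",
    )


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def size_factors(matrix: SignalMatrix) -> np.ndarray:
    """Median-of-ratios per-sample size factors.

    For each feature with positive counts in every sample, the reference is
    its geometric mean across samples; a sample's factor is the median over
    those features of count / reference. Samples sequenced twice as deeply
    get a factor twice as large (up to the geometric-mean normalisation of
    the reference).
    """
    if matrix.kind != "raw_counts":
        raise ValidationError(f"size factors need raw_counts, got {matrix.kind}")
    counts = matrix.values
    all_positive = np.all(counts > 0, axis=1)
    if not np.any(all_positive):
        raise ValidationError(
            "no feature has positive counts in every sample; "
            "size factors are undefined"
        )
    log_counts = np.log(counts[all_positive])
    log_ref = log_counts.mean(axis=1, keepdims=True)  # log geometric mean
    factors = np.exp(np.median(log_counts - log_ref, axis=0))
    return factors


def normalize(matrix: SignalMatrix) -> SignalMatrix:
    """Size-factor-scale a count matrix and apply log2(x + 1).

    The output carries kind="normalized" and stores the size factors, so
    the raw counts are recoverable as (2**value - 1) * factor.
    """
    factors = size_factors(matrix)
    values = np.log2(matrix.values / factors[np.newaxis, :] + 1.0)
    return SignalMatrix(
        feature_ids=list(matrix.feature_ids),
        sample_ids=list(matrix.sample_ids),
        values=values,
        kind="normalized",
        size_factors=factors,
    )
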