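"""Genomic file I/O with a single internal coordinate convention.

Every interval inside the package is 0-based half-open ``[start, end)``,
the BED/narrowPeak convention. GFF3 and GTF are 1-based closed on disk;
conversion happens exactly once, at the parse/write boundary, so no other
module ever reasons about coordinate systems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Gene:
    """A gene with its exon structure collapsed to the gene level.

    Exons are the union of all transcripts' exon records (identical records
    deduplicated, overlapping records kept as-is). The TSS is the 5' end of
    the gene: ``interval.start`` on the plus strand, ``interval.end - 1`` on
    the minus strand. An unstranded gene is treated as plus-stranded for TSS
    purposes.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        for exon in self.exons:
            if exon.chrom != self.interval.chrom:
                raise ValidationError(
                    f"exon chrom {exon.chrom} != gene chrom {self.interval.chrom}"
                )
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ValidationError(
                    f"exon [{exon.start},{exon.end}) escapes gene "
                    f"[{self.interval.start},{self.interval.end}) of {self.gene_id}"
                )

    @property
    def tss(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start


@dataclass
class GeneAnnotation:
    """A collection of genes keyed by gene_id."""

    genes: dict[str, Gene] = field(default_factory=dict)
    source_path: str = ""

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def chroms(self) -> set[str]:
        return {g.interval.chrom for g in self}


@dataclass(frozen=True)
class Peak:
    """One narrowPeak record.

    ``neg_log10_p`` / ``neg_log10_q`` are stored exactly as the format
    carries them (already -log10 transformed). ``summit_offset`` is the
    summit position relative to ``interval.start``; -1 means absent.
    """

    interval: GenomicInterval
    name: str
    signal: float = 0.0
    neg_log10_p: float = 0.0
    neg_log10_q: float = 0.0
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if self.summit_offset != -1 and not 0 <= self.summit_offset < len(self.interval):
            raise ValidationError(
                f"summit_offset {self.summit_offset} outside peak of length "
                f"{len(self.interval)}"
            )
        if self.neg_log10_q < 0:
            raise ValidationError(f"neg_log10_q must be >= 0, got {self.neg_log10_q}")

    @property
    def anchor(self) -> int:
        """Classification anchor: the summit if present, else the midpoint."""
        if self.summit_offset >= 0:
            return self.interval.start + self.summit_offset
        return (self.interval.start + self.interval.end) // 2


@dataclass
class PeakSet:
    """Peaks of one sample, kept sorted by (chrom, start)."""

    sample_id: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        self.peaks = sorted(
            self.peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
        )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            continue
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def parse_gff3(
    path: str | Path,
    feature_type: str = "gene",
    id_attribute: str = "ID",
) -> GeneAnnotation:
    """Read genes (with exons attached through Parent chains) from a GFF3 file.

    GFF3 coordinates are 1-based closed; they are converted to the internal
    0-based half-open convention here. Exons are attached to a gene either
    directly (``Parent=<gene>``) or through one level of transcript features
    (gene -> transcript -> exon) and collapsed to the gene level as the union
    of all transcripts' exon records; identical records are deduplicated but
    overlapping distinct records are not merged.

    Parameters
    ----------
    path:
        GFF3 file.
    feature_type:
        The column-3 feature type to load as genes (usually ``gene``).
    id_attribute:
        The attribute naming each gene (usually ``ID``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such GFF3 file: {path}")

    records: list[tuple[int, str, str, int, int, str, dict[str, str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError(
                    f"GFF3 line has {len(cols)} columns, expected 9",
                    path=str(path), line=lineno,
                )
            try:
                start = int(cols[3])
                end = int(cols[4])
            except ValueError as exc:
                raise FormatError(
                    f"non-integer coordinates: {cols[3]!r}/{cols[4]!r}",
                    path=str(path), line=lineno,
                ) from exc
            if end < start:
                raise FormatError(
                    f"end < start ({end} < {start})", path=str(path), line=lineno
                )
            strand = cols[6] if cols[6] in STRANDS else "."
            records.append(
                (lineno, cols[0], cols[2], start, end, strand,
                 _parse_gff3_attributes(cols[8]))
            )

    # index records by ID and by Parent for the gene -> transcript -> exon walk
    by_id: dict[str, tuple] = {}
    children: dict[str, list[tuple]] = {}
    for rec in records:
        attrs = rec[6]
        if "ID" in attrs:
            by_id[attrs["ID"]] = rec
        for parent in attrs.get("Parent", "").split(","):
            parent = parent.strip()
            if parent:
                children.setdefault(parent, []).append(rec)

    genes: dict[str, Gene] = {}
    for rec in records:
        lineno, chrom, ftype, start, end, strand, attrs = rec
        if ftype != feature_type:
            continue
        if id_attribute not in attrs:
            raise FormatError(
                f"{feature_type} record lacks the {id_attribute!r} attribute",
                path=str(path), line=lineno,
            )
        gene_id = attrs[id_attribute]
        if gene_id in genes:
            raise FormatError(
                f"duplicate gene id {gene_id!r}", path=str(path), line=lineno
            )
        interval = GenomicInterval(chrom, start - 1, end, strand)

        # collect exon records reachable within two Parent hops
        exon_recs: list[tuple] = []
        record_key = attrs.get("ID", gene_id)
        direct = children.get(record_key, [])
        for child in direct:
            if child[2] == "exon":
                exon_recs.append(child)
            else:  # transcript level
                for grandchild in children.get(child[6].get("ID", ""), []):
                    if grandchild[2] == "exon":
                        exon_recs.append(grandchild)
        seen: set[tuple] = set()
        exons: list[GenomicInterval] = []
        for _, echrom, _, estart, eend, estrand, _ in exon_recs:
            key = (echrom, estart, eend, estrand)
            if key in seen:
                continue  # dedupe identical records only; no merging
            seen.add(key)
            exons.append(GenomicInterval(echrom, estart - 1, eend, estrand))
        exons.sort(key=lambda e: (e.start, e.end))
        genes[gene_id] = Gene(gene_id, interval, tuple(exons))

    ann = GeneAnnotation(genes=genes, source_path=str(path))
    _warn_mixed_chrom_styles(ann)
    return ann


def _warn_mixed_chrom_styles(ann: GeneAnnotation) -> None:
    styles = {c.startswith("chr") for c in ann.chroms()}
    if len(styles) > 1:
        logger.warning(
            "annotation mixes 'chr'-prefixed and bare chromosome names; "
            "interval queries against peak files may silently miss"
        )


def write_gff3(annotation: GeneAnnotation, path: str | Path) -> None:
    """Write an annotation back to GFF3 (gene -> mRNA -> exon hierarchy).

    Round-trips through :func:`parse_gff3`: gene intervals and exon records
    come back identical.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in sorted(annotation, key=lambda g: (g.interval.chrom, g.interval.start)):
            iv = gene.interval
            fh.write(
                f"{iv.chrom}\tpeakflow\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={gene.gene_id}\n"
            )
            tx_id = f"{gene.gene_id}.t1"
            fh.write(
                f"{iv.chrom}\tpeakflow\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={tx_id};Parent={gene.gene_id}\n"
            )
            for exon in gene.exons:
                fh.write(
                    f"{exon.chrom}\tpeakflow\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{exon.strand}\t.\tParent={tx_id}\n"
                )


# ---------------------------------------------------------------------------
# narrowPeak
# ---------------------------------------------------------------------------

def parse_narrowpeak(path: str | Path, sample_id: str) -> PeakSet:
    """Read a 10-column ENCODE narrowPeak file into a sorted :class:`PeakSet`.

    Columns: chrom, start, end, name, score, strand, signalValue, pValue,
    qValue, peak (summit offset). Coordinates are already 0-based half-open.
    The p/q columns are already -log10 transformed in the format and are
    stored as-is. A -1 q-value sentinel (missing) is stored as 0 with a
    logged warning; any other negative q-value is a format error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such narrowPeak file: {path}")

    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 10:
                raise FormatError(
                    f"narrowPeak row has {len(cols)} columns, expected 10",
                    path=str(path), line=lineno,
                )
            try:
                start, end = int(cols[1]), int(cols[2])
                signal = float(cols[6])
                neg_p = float(cols[7])
                neg_q = float(cols[8])
                summit = int(cols[9])
            except ValueError as exc:
                raise FormatError(
                    f"malformed numeric field: {line!r}", path=str(path), line=lineno
                ) from exc
            if neg_q < 0:
                if neg_q == -1:
                    logger.warning(
                        "%s:%d: -1 q-value sentinel stored as 0", path, lineno
                    )
                    neg_q = 0.0
                else:
                    raise FormatError(
                        f"negative q-value {neg_q} (only the -1 sentinel is allowed)",
                        path=str(path), line=lineno,
                    )
            strand = cols[5] if cols[5] in STRANDS else "."
            peaks.append(
                Peak(
                    interval=GenomicInterval(cols[0], start, end, strand),
                    name=cols[3],
                    signal=signal,
                    neg_log10_p=max(neg_p, 0.0),
                    neg_log10_q=neg_q,
                    summit_offset=summit,
                )
            )
    return PeakSet(sample_id=sample_id, peaks=peaks)


# ---------------------------------------------------------------------------
# GTF (written for downstream read counting; feature type "exon")
# ---------------------------------------------------------------------------

def write_gtf(intervals: Sequence[tuple[str, GenomicInterval]], path: str | Path) -> None:
    """Write (id, interval) pairs as single-exon GTF records.

    GTF is 1-based closed; gene_id and transcript_id both carry the interval
    id so that interval-level read counters treat each interval as its own
    gene. Writing then reading back yields identical internal intervals.
    """
    ids = [iid for iid, _ in intervals]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate interval ids: {dupes}")
    path = Path(path)
    with open(path, "w") as fh:
        for iid, iv in intervals:
            attrs = f'gene_id "{iid}"; transcript_id "{iid}";'
            fh.write(
                f"{iv.chrom}\tpeakflow\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )


def read_gtf_intervals(path: str | Path) -> list[tuple[str, GenomicInterval]]:
    """Read back a GTF written by :func:`write_gtf` (exon features only)."""
    path = Path(path)
    out: list[tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError(
                    f"GTF line has {len(cols)} columns, expected 9",
                    path=str(path), line=lineno,
                )
            if cols[2] != "exon":
                continue
            attrs = cols[8]
            gene_id = None
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("gene_id"):
                    gene_id = chunk.split(None, 1)[1].strip().strip('"')
            if gene_id is None:
                raise FormatError("missing gene_id attribute", path=str(path), line=lineno)
            strand = cols[6] if cols[6] in STRANDS else "."
            out.append(
                (gene_id, GenomicInterval(cols[0], int(cols[3]) - 1, int(cols[4]), strand))
            )
    return out


# ---------------------------------------------------------------------------
# BED6 (fragment intervals for counting)
# ---------------------------------------------------------------------------

def parse_bed6(path: str | Path) -> list[GenomicInterval]:
    """Read fragment intervals from a BED file (3 to 6 columns used)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such BED file: {path}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(
                    f"BED row has {len(cols)} columns, expected >= 3",
                    path=str(path), line=lineno,
                )
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(
                    f"non-integer BED coordinates: {line!r}",
                    path=str(path), line=lineno,
                ) from exc
            if end <= start or start < 0:
                raise FormatError(
                    f"invalid BED interval [{start}, {end})",
                    path=str(path), line=lineno,
                )
            strand = cols[5] if len(cols) >= 6 and cols[5] in STRANDS else "."
            out.append(GenomicInterval(cols[0], start, end, strand))
    return out


def write_bed6(
    rows: Iterable[tuple[str, GenomicInterval]], path: str | Path, score: int = 0
) -> None:
    """Write (name, interval) rows as BED6."""
    with open(Path(path), "w") as fh:
        for name, iv in rows:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )
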