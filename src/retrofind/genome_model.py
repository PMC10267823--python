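"""Gene models, genomic intervals and feature tracks.

All coordinates inside the package are 0-based, half-open ``[start, end)``.
GTF/GFF3 input (1-based, inclusive) and VCF positions are converted at the
I/O boundary; nothing downstream ever sees a 1-based coordinate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

log = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Raised for malformed or internally inconsistent annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_len(other) > 0

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered chain of non-overlapping exons."""

    transcript_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.chrom != b.chrom:
                raise AnnotationError(
                    f"transcript {self.transcript_id} spans chromosomes"
                )
            if b.start < a.end:
                raise AnnotationError(
                    f"transcript {self.transcript_id} exons unsorted or overlapping"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def transcript_length(self) -> int:
        """Sum of exon lengths — the spliced (mRNA) length."""
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with its genomic span and one or more transcript isoforms."""

    gene_id: str
    gene_name: str
    span: GenomicInterval
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id} has no transcripts")
        for tx in self.transcripts:
            for exon in tx.exons:
                if not self.span.contains(exon):
                    raise AnnotationError(
                        f"exon {exon.chrom}:{exon.start}-{exon.end} of "
                        f"{tx.transcript_id} lies outside gene {self.gene_id} span"
                    )

    @property
    def gene_length(self) -> int:
        """Genomic footprint of the gene; the distance unit used when
        deciding whether a breakpoint partner is far enough away to be an
        insertion rather than an intragenic event."""
        return self.span.end - self.span.start

    @property
    def chrom(self) -> str:
        return self.span.chrom

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for tx in self.transcripts:
            if tx.transcript_id == transcript_id:
                return tx
        raise KeyError(transcript_id)


def derive_introns(transcript: TranscriptModel) -> list[GenomicInterval]:
    """Return the gaps between consecutive exons (n exons → n−1 introns)."""
    introns = []
    for a, b in zip(transcript.exons, transcript.exons[1:]):
        introns.append(GenomicInterval(a.chrom, a.end, b.start, a.strand))
    return introns


def assign_to_exon(
    read_interval: GenomicInterval, transcript: TranscriptModel
) -> Optional[int]:
    """Index of the exon containing at least half of the read's bases.

    Returns ``None`` when no exon reaches the 50% fraction (e.g. an intronic
    read, or a read straddling an exon edge with most bases outside).
    """
    return assign_blocks_to_exon([(read_interval.start, read_interval.end)],
                                 read_interval.chrom, transcript)


def assign_blocks_to_exon(
    blocks: Sequence[tuple[int, int]], chrom: str, transcript: TranscriptModel
) -> Optional[int]:
    """Exon assignment for a (possibly gapped) alignment given its aligned
    blocks; the 50% rule applies to the total aligned bases."""
    if chrom != transcript.chrom:
        return None
    total = sum(e - s for s, e in blocks)
    if total <= 0:
        return None
    best_idx, best_overlap = None, 0
    for i, exon in enumerate(transcript.exons):
        ov = sum(max(0, min(e, exon.end) - max(s, exon.start)) for s, e in blocks)
        if ov > best_overlap:
            best_idx, best_overlap = i, ov
    if best_idx is not None and 2 * best_overlap >= total:
        return best_idx
    return None


@dataclass
class FeatureTrack:
    """A named, position-sorted set of genomic intervals (one feature class).

    Used both for enrichment feature classes (segmental duplications,
    reference processed pseudogenes, ...) and for generic interval lookups.
    """

    name: str
    intervals: tuple[GenomicInterval, ...]
    _trees: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.intervals = tuple(
            sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        )
        for iv in self.intervals:
            tree = self._trees.setdefault(iv.chrom, IntervalTree())
            tree.addi(iv.start, iv.end, iv)

    @property
    def total_bases(self) -> int:
        """Union length of the track (overlaps counted once)."""
        total = 0
        cur_chrom, cur_start, cur_end = None, 0, 0
        for iv in self.intervals:
            if iv.chrom != cur_chrom or iv.start > cur_end:
                total += cur_end - cur_start
                cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
            else:
                cur_end = max(cur_end, iv.end)
        total += cur_end - cur_start
        return total


def intersect(site: GenomicInterval, track: FeatureTrack) -> list[GenomicInterval]:
    """All track intervals overlapping ``site`` (empty for unknown chrom)."""
    tree = track._trees.get(site.chrom)
    if tree is None:
        return []
    hits = [h.data for h in tree.overlap(site.start, site.end)]
    hits.sort(key=lambda iv: (iv.start, iv.end))
    return hits


# ---------------------------------------------------------------------------
# Annotation I/O


def _parse_gtf_attributes(attr: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise AnnotationError(f"malformed GTF attribute {chunk!r} at line {lineno}")
        out[parts[0]] = parts[1].strip().strip('"')
    return out


def _parse_gff3_attributes(attr: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise AnnotationError(f"malformed GFF3 attribute {chunk!r} at line {lineno}")
        key, value = chunk.split("=", 1)
        out[key] = value
    return out


def load_gene_models(annotation_path: str | Path) -> dict[str, GeneModel]:
    """Parse a GenCode-style GTF or GFF3 into gene models keyed by gene_id.

    Only ``gene`` / ``transcript`` (or ``mRNA``) / ``exon`` records are used.
    Coordinates are converted from the format's 1-based inclusive convention
    to internal 0-based half-open. A gene record is optional: gene spans are
    widened to cover their exons when absent.
    """
    path = Path(annotation_path)
    gff3 = path.suffix.lower() in (".gff", ".gff3") or _sniff_gff3(path)
    parse_attrs = _parse_gff3_attributes if gff3 else _parse_gtf_attributes

    gene_meta: dict[str, dict] = {}
    tx_exons: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    gff3_id_to_gene: dict[str, str] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"expected 9 columns at line {lineno}")
            chrom, _src, feature, start, end, _score, strand, _frame, attr = fields
            if feature not in ("gene", "transcript", "mRNA", "exon"):
                continue
            try:
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except ValueError as exc:
                raise AnnotationError(f"bad coordinates at line {lineno}: {exc}")
            attrs = parse_attrs(attr, lineno)
            if gff3:
                gene_id = attrs.get("gene_id")
                tx_id = attrs.get("transcript_id")
                if feature == "gene":
                    gid = gene_id or attrs.get("ID")
                    if gid is None:
                        raise AnnotationError(f"gene without ID at line {lineno}")
                    if "ID" in attrs:
                        gff3_id_to_gene[attrs["ID"]] = gid
                    gene_meta[gid] = {
                        "span": iv,
                        "name": attrs.get("gene_name", attrs.get("Name", gid)),
                    }
                elif feature in ("transcript", "mRNA"):
                    tid = tx_id or attrs.get("ID")
                    gid = gene_id or gff3_id_to_gene.get(attrs.get("Parent", ""))
                    if gid is None:
                        gid = attrs.get("Parent")
                    if tid is None or gid is None:
                        raise AnnotationError(
                            f"transcript without ID/Parent at line {lineno}"
                        )
                    if "ID" in attrs:
                        gff3_id_to_gene[attrs["ID"]] = gid
                    tx_gene[tid] = gid
                    tx_exons.setdefault(tid, [])
                else:  # exon
                    tid = tx_id or attrs.get("Parent")
                    if tid is None:
                        raise AnnotationError(f"exon without Parent at line {lineno}")
                    tx_exons.setdefault(tid, []).append(iv)
            else:
                gene_id = attrs.get("gene_id")
                if gene_id is None:
                    raise AnnotationError(f"record without gene_id at line {lineno}")
                if feature == "gene":
                    gene_meta[gene_id] = {
                        "span": iv,
                        "name": attrs.get("gene_name", gene_id),
                    }
                else:
                    tx_id = attrs.get("transcript_id")
                    if tx_id is None:
                        raise AnnotationError(
                            f"record without transcript_id at line {lineno}"
                        )
                    tx_gene[tx_id] = gene_id
                    if feature == "exon":
                        tx_exons.setdefault(tx_id, []).append(iv)
                    else:
                        tx_exons.setdefault(tx_id, [])

    genes: dict[str, GeneModel] = {}
    gene_txs: dict[str, list[TranscriptModel]] = {}
    for tid, exons in tx_exons.items():
        if not exons:
            log.warning("transcript %s has no exon records; skipped", tid)
            continue
        exons.sort(key=lambda e: e.start)
        gid = tx_gene.get(tid)
        if gid is None:
            raise AnnotationError(f"exons of {tid} have no parent gene")
        gene_txs.setdefault(gid, []).append(TranscriptModel(tid, tuple(exons)))

    for gid, txs in gene_txs.items():
        txs.sort(key=lambda t: t.transcript_id)
        meta = gene_meta.get(gid)
        lo = min(t.exons[0].start for t in txs)
        hi = max(t.exons[-1].end for t in txs)
        if meta is None:
            span = GenomicInterval(txs[0].chrom, lo, hi, txs[0].strand)
            name = gid
        else:
            span, name = meta["span"], meta["name"]
        genes[gid] = GeneModel(gid, name, span, tuple(txs))

    for gid in gene_meta:
        if gid not in genes:
            log.warning("gene %s has no transcripts with exons; skipped", gid)
    return genes


def _sniff_gff3(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("##gff-version"):
                return True
            if not line.startswith("#"):
                return False
    return False


def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models back out as GTF (round-trip safe with the loader)."""
    with open(path, "w") as fh:
        for gene in sorted(genes, key=lambda g: (g.chrom, g.span.start, g.gene_id)):
            attrs = f'gene_id "{gene.gene_id}"; gene_name "{gene.gene_name}";'
            fh.write(
                "\t".join(
                    [gene.chrom, "retrofind", "gene", str(gene.span.start + 1),
                     str(gene.span.end), ".", gene.span.strand, ".", attrs]
                ) + "\n"
            )
            for tx in gene.transcripts:
                tattrs = attrs + f' transcript_id "{tx.transcript_id}";'
                fh.write(
                    "\t".join(
                        [gene.chrom, "retrofind", "transcript",
                         str(tx.span.start + 1), str(tx.span.end), ".",
                         tx.strand, ".", tattrs]
                    ) + "\n"
                )
                for exon in tx.exons:
                    fh.write(
                        "\t".join(
                            [gene.chrom, "retrofind", "exon",
                             str(exon.start + 1), str(exon.end), ".",
                             exon.strand, ".", tattrs]
                        ) + "\n"
                    )


def read_bed(path: str | Path, name: str | None = None) -> FeatureTrack:
    """Read a 3- or 6-column BED (or any tab file whose first three columns
    are chrom/start/end in BED convention) into a FeatureTrack."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise AnnotationError(f"BED line with <3 columns: {line!r}")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            intervals.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return FeatureTrack(name or Path(path).stem, tuple(intervals))
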