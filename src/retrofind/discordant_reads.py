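"""Extraction of exon-discordant read pairs from WGS alignments.

A non-reference retrocopy has no home in the reference, so its reads map
back onto the parent gene's exons. A read pair drawn from an exon-exon
junction fragment of the retrocopy therefore maps with its two mates in
different exons and a template length inflated by the skipped intron(s).
This module scans an alignment file for exactly that signature: both mates
within one gene, assigned to different exons of one transcript, with a
template length above a library-derived threshold.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pysam

from .genome_model import (
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    assign_blocks_to_exon,
)

log = logging.getLogger(__name__)

#: pairs with template length outside (0, this · read_length) are treated as
#: mapping artefacts and excluded from library-statistics estimation
_TLEN_SANITY_FACTOR = 1000

DEFAULT_MIN_MAPQ = 10
#: floor on the discordance threshold; an informative pair must at least
#: plausibly span an intron
MIN_INSERT_FLOOR = 1000


@dataclass(frozen=True)
class Mate:
    """One aligned mate: its aligned blocks and mapping quality."""

    interval: GenomicInterval
    mapq: int
    blocks: tuple[tuple[int, int], ...]

    @classmethod
    def from_interval(cls, interval: GenomicInterval, mapq: int = 60) -> "Mate":
        return cls(interval, mapq, ((interval.start, interval.end),))

    @property
    def aligned_bases(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass(frozen=True)
class AlignedPair:
    read_id: str
    mate1: Mate
    mate2: Mate
    template_length: int

    def __post_init__(self) -> None:
        if self.template_length < 0:
            raise ValueError("template_length must be >= 0")


@dataclass(frozen=True)
class LibraryStats:
    """Insert-size distribution of the sequencing library."""

    mean_insert: float
    sd_insert: float
    n_sampled: int
    warning: Optional[str] = None


@dataclass(frozen=True)
class DiscordantPair:
    """A read pair supporting a retrocopy of ``gene_id``.

    ``exon_index_*`` is the exon each mate was assigned to on
    ``transcript_id`` (None when the mate failed the assignment rule);
    ``exon_bases_*`` is the number of that mate's aligned bases falling in
    its assigned exon.
    """

    pair: AlignedPair
    gene_id: str
    transcript_id: str
    exon_index_1: Optional[int]
    exon_index_2: Optional[int]
    exon_bases_1: int
    exon_bases_2: int

    def __post_init__(self) -> None:
        if self.exon_index_1 is not None and self.exon_index_1 == self.exon_index_2:
            raise ValueError("mates assigned to the same exon are not discordant")


def estimate_library_stats(
    alignments: str | Path | pysam.AlignmentFile, sample_size: int = 10000
) -> LibraryStats:
    """Estimate insert-size mean/sd from the first ``sample_size`` proper pairs.

    Deterministic for a fixed file: pairs are taken in file order, each pair
    counted once (via its positive template length). Template lengths outside
    a generous sanity window are excluded as artefacts.
    """
    own = isinstance(alignments, (str, Path))
    af = pysam.AlignmentFile(str(alignments)) if own else alignments
    tlens: list[int] = []
    try:
        for rec in af.fetch(until_eof=True):
            if (
                rec.is_unmapped
                or not rec.is_proper_pair
                or rec.is_secondary
                or rec.is_supplementary
                or rec.is_duplicate
            ):
                continue
            tlen = rec.template_length
            if tlen <= 0:  # count each pair once, from the leftmost mate
                continue
            read_len = rec.query_length or rec.infer_query_length() or 0
            if read_len and tlen >= _TLEN_SANITY_FACTOR * read_len:
                continue
            tlens.append(tlen)
            if len(tlens) >= sample_size:
                break
    finally:
        if own:
            af.close()
    if not tlens:
        raise ValueError(
            "no proper pairs found; supply an explicit insert-size threshold "
            "(min_insert_override) instead"
        )
    n = len(tlens)
    mean = sum(tlens) / n
    var = sum((t - mean) ** 2 for t in tlens) / n
    warning = None
    if n < 1000:
        warning = f"only {n} proper pairs sampled; estimates may be unstable"
    return LibraryStats(mean, math.sqrt(var), n, warning)


def discordance_threshold(
    stats: Optional[LibraryStats], min_insert_override: Optional[int] = None
) -> float:
    """Template-length cut above which a pair counts as discordant."""
    if min_insert_override is not None:
        return float(min_insert_override)
    if stats is None:
        raise ValueError("need LibraryStats or an explicit min_insert_override")
    return max(float(MIN_INSERT_FLOOR), stats.mean_insert + 3.0 * stats.sd_insert)


def _evaluate_pair(
    pair: AlignedPair, gene: GeneModel
) -> Optional[tuple[TranscriptModel, int, int]]:
    """Best transcript on which the pair is exon-discordant, or None.

    Among transcripts where both mates assign to different exons, the one
    spanning the most exons (largest index gap) is chosen; ties break to the
    lexicographically smallest transcript_id (transcripts are stored sorted).
    """
    best: Optional[tuple[TranscriptModel, int, int]] = None
    best_spread = -1
    for tx in gene.transcripts:
        i1 = assign_blocks_to_exon(pair.mate1.blocks, pair.mate1.interval.chrom, tx)
        i2 = assign_blocks_to_exon(pair.mate2.blocks, pair.mate2.interval.chrom, tx)
        if i1 is None or i2 is None or i1 == i2:
            continue
        spread = abs(i1 - i2)
        if spread > best_spread:
            best, best_spread = (tx, i1, i2), spread
    return best


def _exon_bases(mate: Mate, exon: GenomicInterval) -> int:
    return sum(
        max(0, min(e, exon.end) - max(s, exon.start)) for s, e in mate.blocks
    )


def evaluate_pair_against_genes(
    pair: AlignedPair, genes: Iterable[GeneModel], threshold: float, min_mapq: int
) -> list[DiscordantPair]:
    """Apply the three discordance conditions to one candidate pair.

    Emitted iff (a) both mates assign to different exons of one transcript,
    (b) template length exceeds ``threshold``, (c) both mapping qualities are
    at least ``min_mapq``. A pair is evaluated against every gene whose span
    contains both mates and emitted once per such gene.
    """
    out: list[DiscordantPair] = []
    if pair.template_length <= threshold:
        return out
    if pair.mate1.mapq < min_mapq or pair.mate2.mapq < min_mapq:
        return out
    for gene in genes:
        if not (
            gene.span.contains(pair.mate1.interval)
            and gene.span.contains(pair.mate2.interval)
        ):
            continue
        hit = _evaluate_pair(pair, gene)
        if hit is None:
            continue
        tx, i1, i2 = hit
        out.append(
            DiscordantPair(
                pair=pair,
                gene_id=gene.gene_id,
                transcript_id=tx.transcript_id,
                exon_index_1=i1,
                exon_index_2=i2,
                exon_bases_1=_exon_bases(pair.mate1, tx.exons[i1]),
                exon_bases_2=_exon_bases(pair.mate2, tx.exons[i2]),
            )
        )
    return out


def _record_to_mate(rec: pysam.AlignedSegment) -> Mate:
    blocks = tuple(rec.get_blocks())
    return Mate(
        GenomicInterval(rec.reference_name, rec.reference_start, rec.reference_end),
        rec.mapping_quality,
        blocks,
    )


def extract_discordant_pairs(
    alignments: str | Path,
    genes: dict[str, GeneModel] | Iterable[GeneModel],
    stats: Optional[LibraryStats] = None,
    min_insert_override: Optional[int] = None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> list[DiscordantPair]:
    """Scan an alignment file and return all exon-discordant pairs.

    Secondary, supplementary, duplicate and unmapped records are ignored.
    If ``stats`` is omitted it is estimated from the file first. The
    threshold is ``min_insert_override`` when given, else
    ``max(1000, mean + 3·sd)``.
    """
    if isinstance(genes, dict):
        gene_list = list(genes.values())
    else:
        gene_list = list(genes)
    if min_insert_override is None and stats is None:
        stats = estimate_library_stats(alignments)
    threshold = discordance_threshold(stats, min_insert_override)

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_list:
        by_chrom.setdefault(g.chrom, []).append(g)

    pending: dict[str, pysam.AlignedSegment] = {}
    out: list[DiscordantPair] = []
    with pysam.AlignmentFile(str(alignments)) as af:
        for rec in af.fetch(until_eof=True):
            if (
                rec.is_unmapped
                or rec.mate_is_unmapped
                or not rec.is_paired
                or rec.is_secondary
                or rec.is_supplementary
                or rec.is_duplicate
            ):
                continue
            other = pending.pop(rec.query_name, None)
            if other is None:
                pending[rec.query_name] = rec
                continue
            if other.reference_name != rec.reference_name:
                continue
            first, second = sorted(
                (other, rec), key=lambda r: (r.reference_start, r.is_read2)
            )
            pair = AlignedPair(
                read_id=rec.query_name,
                mate1=_record_to_mate(first),
                mate2=_record_to_mate(second),
                template_length=abs(rec.template_length),
            )
            out.extend(
                evaluate_pair_against_genes(
                    pair, by_chrom.get(rec.reference_name, ()), threshold, min_mapq
                )
            )
    out.sort(
        key=lambda d: (d.gene_id, d.transcript_id, d.pair.mate1.interval.start,
                       d.pair.read_id)
    )
    return out


PAIR_TSV_COLUMNS = [
    "read_id", "gene_id", "transcript_id", "exon_index_1", "exon_index_2",
    "chrom", "start_1", "end_1", "start_2", "end_2",
    "exon_bases_1", "exon_bases_2", "template_length",
]


def write_pairs_tsv(pairs: Iterable[DiscordantPair], path: str | Path,
                    header_lines: Iterable[str] = ()) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PAIR_TSV_COLUMNS)
        for d in pairs:
            writer.writerow([
                d.pair.read_id, d.gene_id, d.transcript_id,
                d.exon_index_1 if d.exon_index_1 is not None else ".",
                d.exon_index_2 if d.exon_index_2 is not None else ".",
                d.pair.mate1.interval.chrom,
                d.pair.mate1.interval.start, d.pair.mate1.interval.end,
                d.pair.mate2.interval.start, d.pair.mate2.interval.end,
                d.exon_bases_1, d.exon_bases_2, d.pair.template_length,
            ])


def read_pairs_tsv(path: str | Path) -> list[DiscordantPair]:
    pairs: list[DiscordantPair] = []
    with open(path) as fh:
        reader = csv.reader(
            (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
        )
        header = next(reader, None)
        if header != PAIR_TSV_COLUMNS:
            raise ValueError(f"unexpected pair-TSV header in {path}")
        for row in reader:
            rec = dict(zip(PAIR_TSV_COLUMNS, row))
            m1 = Mate.from_interval(
                GenomicInterval(rec["chrom"], int(rec["start_1"]), int(rec["end_1"]))
            )
            m2 = Mate.from_interval(
                GenomicInterval(rec["chrom"], int(rec["start_2"]), int(rec["end_2"]))
            )
            pairs.append(
                DiscordantPair(
                    pair=AlignedPair(rec["read_id"], m1, m2,
                                     int(rec["template_length"])),
                    gene_id=rec["gene_id"],
                    transcript_id=rec["transcript_id"],
                    exon_index_1=None if rec["exon_index_1"] == "." else int(rec["exon_index_1"]),
                    exon_index_2=None if rec["exon_index_2"] == "." else int(rec["exon_index_2"]),
                    exon_bases_1=int(rec["exon_bases_1"]),
                    exon_bases_2=int(rec["exon_bases_2"]),
                )
            )
    return pairs
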