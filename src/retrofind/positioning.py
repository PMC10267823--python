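"""Insertion-site positioning from SV breakpoints, and deletion-miscall counts.

The junction between a retrocopy and its integration site produces breakend
(BND) calls linking the neighbourhood of the parent gene's termini to the
insertion locus. A breakpoint call is insert-site evidence when one end lies
near a parent-gene terminus and the partner end is on another chromosome or
at least one gene length away; the partner's location is the evidence.
Evidence within 500 bp is collapsed into a single insert site
(single-linkage), sites further apart stay unique.

Short-read SV callers also emit one spurious deletion call per intron of the
parent gene (exon-only coverage looks like the introns were deleted); this
module counts those per gene, separating the "high-priority" subset that
overlaps an exon and would be flagged as truncating downstream.
"""

from __future__ import annotations

import logging
import re
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pysam

from .genome_model import GeneModel, GenomicInterval, derive_introns

log = logging.getLogger(__name__)

DEFAULT_TERMINUS_WINDOW = 1000
DEFAULT_MAX_GAP = 500

_BND_RE = re.compile(r"[\[\]]([^\[\]:]+):(\d+)[\[\]]")


@dataclass
class BreakpointCall:
    """One SV call reduced to its two breakend coordinates (0-based)."""

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    sv_type: str  # DEL, BND, or other
    filter: str = "PASS"
    sample_id: Optional[str] = None
    overlaps_exon: bool = False

    def __post_init__(self) -> None:
        if self.pos_a < 0 or self.pos_b < 0:
            raise ValueError("breakend positions must be >= 0")
        if self.sv_type == "DEL":
            if self.chrom_a != self.chrom_b or not self.pos_a < self.pos_b:
                raise ValueError("DEL requires chrom_a == chrom_b and pos_a < pos_b")


@dataclass(frozen=True)
class InsertEvidence:
    chrom: str
    position: int
    sample_id: Optional[str] = None


@dataclass
class InsertSiteCluster:
    """A collapsed insertion locus for one parent gene."""

    gene_id: str
    chrom: str
    position: int                 # median of members (lower middle)
    members: list[int] = field(default_factory=list)
    sample_count: int = 0


def load_breakpoint_calls(
    vcf_path: str | Path, sample_id: Optional[str] = None
) -> list[BreakpointCall]:
    """Parse DEL and BND records from a VCF into breakpoint calls.

    DEL: POS and INFO/END; BND: POS and the partner coordinate from the
    bracketed ALT. Symbolic non-BND ALTs without an END are skipped with a
    warning. Positions are converted to 0-based.
    """
    calls: list[BreakpointCall] = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        for rec in vf:
            svtype = rec.info.get("SVTYPE")
            if svtype == "BND" or any("[" in a or "]" in a for a in (rec.alts or ())):
                m = _BND_RE.search(rec.alts[0])
                if m is None:
                    log.warning("unparseable BND ALT %s at %s:%s; skipped",
                                rec.alts[0], rec.chrom, rec.pos)
                    continue
                calls.append(
                    BreakpointCall(
                        chrom_a=rec.chrom,
                        pos_a=rec.pos - 1,
                        chrom_b=m.group(1),
                        pos_b=int(m.group(2)) - 1,
                        sv_type="BND",
                        filter=";".join(rec.filter.keys()) or "PASS",
                        sample_id=sample_id,
                    )
                )
            elif svtype == "DEL":
                end = rec.stop  # pysam: 0-based exclusive end from INFO/END
                if end is None or end <= rec.pos - 1:
                    log.warning("DEL without usable END at %s:%s; skipped",
                                rec.chrom, rec.pos)
                    continue
                calls.append(
                    BreakpointCall(
                        chrom_a=rec.chrom,
                        pos_a=rec.pos - 1,
                        chrom_b=rec.chrom,
                        pos_b=end,
                        sv_type="DEL",
                        filter=";".join(rec.filter.keys()) or "PASS",
                        sample_id=sample_id,
                    )
                )
            elif svtype is not None:
                # other SV classes carry no retrocopy signal here
                continue
    return calls


def _near_terminus(chrom: str, pos: int, gene: GeneModel, window: int) -> bool:
    if chrom != gene.chrom:
        return False
    return (
        abs(pos - gene.span.start) <= window or abs(pos - gene.span.end) <= window
    )


def find_insert_breakpoints(
    calls: Iterable[BreakpointCall],
    gene: GeneModel,
    terminus_window: int = DEFAULT_TERMINUS_WINDOW,
) -> list[InsertEvidence]:
    """Insert-site evidence for one parent gene.

    A call contributes iff one breakend lies within ``terminus_window`` of
    the gene's start or end AND the partner is on a different chromosome or
    at least ``gene_length`` away from it; the partner's location is emitted.
    Both end orderings are checked.
    """
    out: list[InsertEvidence] = []
    seen: set[tuple[str, int, Optional[str]]] = set()
    for call in calls:
        ends = (
            (call.chrom_a, call.pos_a, call.chrom_b, call.pos_b),
            (call.chrom_b, call.pos_b, call.chrom_a, call.pos_a),
        )
        for ca, pa, cb, pb in ends:
            if not _near_terminus(ca, pa, gene, terminus_window):
                continue
            if cb != ca or abs(pb - pa) >= gene.gene_length:
                key = (cb, pb, call.sample_id)
                if key not in seen:
                    seen.add(key)
                    out.append(InsertEvidence(cb, pb, call.sample_id))
    return out


def cluster_insert_sites(
    evidence: Sequence[InsertEvidence] | Sequence[tuple[str, int]],
    gene_id: str = "",
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[InsertSiteCluster]:
    """Single-linkage collapse of insert-site evidence per chromosome.

    Positions are sorted; a new cluster starts whenever the gap to the
    previous position exceeds ``max_gap`` (so positions exactly ``max_gap``
    apart collapse, ``max_gap + 1`` stay unique — chains merge transitively).
    The representative position is the median (lower of the two middles for
    even member counts).
    """
    normalized: list[InsertEvidence] = [
        ev if isinstance(ev, InsertEvidence) else InsertEvidence(ev[0], ev[1])
        for ev in evidence
    ]
    by_chrom: dict[str, list[InsertEvidence]] = {}
    for ev in normalized:
        by_chrom.setdefault(ev.chrom, []).append(ev)

    clusters: list[InsertSiteCluster] = []
    for chrom in sorted(by_chrom):
        evs = sorted(by_chrom[chrom], key=lambda e: e.position)
        group: list[InsertEvidence] = []
        for ev in evs:
            if group and ev.position - group[-1].position > max_gap:
                clusters.append(_finish_cluster(gene_id, chrom, group))
                group = []
            group.append(ev)
        if group:
            clusters.append(_finish_cluster(gene_id, chrom, group))
    return clusters


def _finish_cluster(
    gene_id: str, chrom: str, group: list[InsertEvidence]
) -> InsertSiteCluster:
    positions = [ev.position for ev in group]
    return InsertSiteCluster(
        gene_id=gene_id,
        chrom=chrom,
        position=statistics.median_low(positions),
        members=positions,
        sample_count=len({ev.sample_id for ev in group if ev.sample_id is not None}),
    )


def count_deletion_calls(
    calls: Iterable[BreakpointCall], gene: GeneModel
) -> tuple[int, int]:
    """(total, high_priority) deletion calls over a gene for one sample.

    total: DEL calls whose span overlaps the gene span. high_priority: the
    subset overlapping at least one exon (any transcript) — the calls a
    consequence annotator would flag as truncating.
    """
    total = high = 0
    exons = [e for tx in gene.transcripts for e in tx.exons]
    for call in calls:
        if call.sv_type != "DEL":
            continue
        iv = GenomicInterval(call.chrom_a, call.pos_a, call.pos_b)
        if not iv.overlaps(gene.span):
            continue
        total += 1
        call.overlaps_exon = any(iv.overlaps(e) for e in exons)
        if call.overlaps_exon:
            high += 1
    return total, high


def positioned_fraction(
    candidate_keys: Iterable[tuple[str, str]],
    clusters: Mapping[tuple[str, str], Sequence[InsertSiteCluster]],
) -> Optional[float]:
    """Fraction of (sample, gene) candidates with at least one insert-site
    cluster; None ("not applicable") for an empty candidate set."""
    keys = list(candidate_keys)
    if not keys:
        return None
    positioned = sum(1 for key in keys if clusters.get(key))
    return positioned / len(keys)


def write_clusters_bed(
    clusters: Iterable[InsertSiteCluster], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for c in sorted(clusters, key=lambda c: (c.chrom, c.position, c.gene_id)):
            fh.write(
                f"{c.chrom}\t{c.position}\t{c.position + 1}\t{c.gene_id}\t{c.sample_count}\n"
            )


def write_deletion_counts_tsv(
    counts: Mapping[str, tuple[float, float, int, int]], path: str | Path
) -> None:
    """Per-gene deletion-miscall summary across a cohort: average and maximum
    of the total and high-priority counts."""
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tavg_deletion_calls\tavg_high_priority\t"
            "max_deletion_calls\tmax_high_priority\n"
        )
        for gid in sorted(counts):
            avg_t, avg_h, max_t, max_h = counts[gid]
            fh.write(f"{gid}\t{avg_t:.2f}\t{avg_h:.2f}\t{max_t}\t{max_h}\n")


def summarize_deletion_counts(
    per_sample_counts: Mapping[str, Mapping[str, tuple[int, int]]]
) -> dict[str, tuple[float, float, int, int]]:
    """Aggregate per-sample (total, high) deletion counts into per-gene
    (avg_total, avg_high, max_total, max_high) across samples."""
    by_gene: dict[str, list[tuple[int, int]]] = {}
    for counts in per_sample_counts.values():
        for gid, th in counts.items():
            by_gene.setdefault(gid, []).append(th)
    out = {}
    for gid, values in by_gene.items():
        totals = [t for t, _ in values]
        highs = [h for _, h in values]
        out[gid] = (
            sum(totals) / len(totals),
            sum(highs) / len(highs),
            max(totals),
            max(highs),
        )
    return out
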