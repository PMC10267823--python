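"""Transcript-level support quantification and retrocopy candidate calling.

Support is quantified by projecting the extracted discordant mates onto the
transcript they are discordant on: each successfully exon-assigned mate adds
one read and its in-exon aligned bases to that transcript. A transcript is a
processed-pseudogene candidate when it accumulates more than ``min_reads``
supporting reads (strict; 20 by default) and a mean projected coverage of at
least ``min_coverage`` (3X by default). The read threshold ensures the
evidence is an exon chain rather than a single deletion-like event; the
coverage threshold mirrors the minimum support typical SV callers demand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .discordant_reads import DiscordantPair
from .genome_model import GeneModel

DEFAULT_MIN_READS = 20      # exclusive: a candidate needs *more than* this
DEFAULT_MIN_COVERAGE = 3.0  # inclusive: *at least* this mean depth


@dataclass(frozen=True)
class TranscriptSupport:
    transcript_id: str
    gene_id: str
    read_count: int          # individual mate reads, not pairs
    aligned_bases: int
    mean_coverage: float     # aligned_bases / transcript_length, in X

    def __post_init__(self) -> None:
        if self.read_count < 0 or self.mean_coverage < 0:
            raise ValueError("support must be non-negative")


@dataclass(frozen=True)
class PseudogeneCandidate:
    sample_id: str
    gene_id: str
    gene_name: str
    transcript_id: str
    read_count: int
    mean_coverage: float
    population: Optional[str] = None


def quantify_support(
    pairs: Iterable[DiscordantPair], genes: Mapping[str, GeneModel]
) -> list[TranscriptSupport]:
    """Aggregate per-transcript read counts and projected coverage.

    A mate contributes iff its exon assignment succeeded on the pair's
    transcript; its contribution to coverage is its aligned bases clipped to
    the assigned exon. Transcripts with zero support are omitted.
    """
    counts: dict[tuple[str, str], int] = {}
    bases: dict[tuple[str, str], int] = {}
    for pair in pairs:
        gene = genes.get(pair.gene_id)
        if gene is None:
            raise KeyError(f"pair references unknown gene {pair.gene_id}")
        try:
            gene.transcript(pair.transcript_id)
        except KeyError:
            raise KeyError(
                f"pair references unknown transcript {pair.transcript_id}"
            ) from None
        key = (pair.gene_id, pair.transcript_id)
        for idx, nbases in (
            (pair.exon_index_1, pair.exon_bases_1),
            (pair.exon_index_2, pair.exon_bases_2),
        ):
            if idx is None:
                continue
            counts[key] = counts.get(key, 0) + 1
            bases[key] = bases.get(key, 0) + nbases
    out = []
    for (gid, tid), n in sorted(counts.items()):
        tx_len = genes[gid].transcript(tid).transcript_length
        out.append(
            TranscriptSupport(
                transcript_id=tid,
                gene_id=gid,
                read_count=n,
                aligned_bases=bases[(gid, tid)],
                mean_coverage=bases[(gid, tid)] / tx_len,
            )
        )
    return out


def call_candidates(
    support: Iterable[TranscriptSupport],
    genes: Mapping[str, GeneModel],
    sample_id: str,
    min_reads: int = DEFAULT_MIN_READS,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[PseudogeneCandidate]:
    """Candidates for one sample: read_count > min_reads AND coverage >= min_coverage.

    When several transcripts of a gene pass, only the one with the highest
    read count is reported (ties to the lexicographically smallest
    transcript_id), so the output has at most one row per parent gene.
    """
    best: dict[str, TranscriptSupport] = {}
    for s in support:
        if not (s.read_count > min_reads and s.mean_coverage >= min_coverage):
            continue
        cur = best.get(s.gene_id)
        if (
            cur is None
            or s.read_count > cur.read_count
            or (s.read_count == cur.read_count and s.transcript_id < cur.transcript_id)
        ):
            best[s.gene_id] = s
    return [
        PseudogeneCandidate(
            sample_id=sample_id,
            gene_id=s.gene_id,
            gene_name=genes[s.gene_id].gene_name,
            transcript_id=s.transcript_id,
            read_count=s.read_count,
            mean_coverage=s.mean_coverage,
        )
        for _, s in sorted(best.items())
    ]


COHORT_COLUMNS = [
    "sample_id", "population", "gene_id", "gene_name",
    "transcript_id", "read_count", "mean_coverage",
]


def merge_cohort(
    candidates_by_sample: Mapping[str, Iterable[PseudogeneCandidate]],
    populations: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Long-format cohort table: one row per (sample, parent gene) candidate."""
    rows = []
    seen: set[tuple[str, str]] = set()
    for sample_id in sorted(candidates_by_sample):
        pop = populations.get(sample_id) if populations else None
        for c in candidates_by_sample[sample_id]:
            key = (sample_id, c.gene_id)
            if key in seen:
                raise ValueError(f"duplicate candidate row for {key}")
            seen.add(key)
            rows.append(
                {
                    "sample_id": sample_id,
                    "population": pop if pop is not None else c.population,
                    "gene_id": c.gene_id,
                    "gene_name": c.gene_name,
                    "transcript_id": c.transcript_id,
                    "read_count": c.read_count,
                    "mean_coverage": c.mean_coverage,
                }
            )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
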