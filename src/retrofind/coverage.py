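"""Read-depth validation of retrocopy candidates.

A genome carrying an extra intron-less copy of a gene shows elevated depth
over the parent gene's exons but not its introns, because the retrocopy's
reads map back onto the exons. On a diploid background, one extra copy adds
half a haploid dose: exons sit at 3 copies against 2 intron copies, an
exon/intron ratio of 1.5; two extra copies give 2.0; a non-carrier sits at
1.0. Depth is normalised per individual to the mean depth of a reference
chromosome and doubled, putting the copy-neutral state at 2.0 on a diploid
scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .genome_model import GenomicInterval, TranscriptModel, derive_introns


@dataclass
class DepthProfile:
    """Per-base depth over a gene span, raw and diploid-normalised."""

    gene_id: str
    span: GenomicInterval
    raw_depth: np.ndarray
    norm_depth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.raw_depth) != self.span.length:
            raise ValueError("depth array length must equal span length")


@dataclass
class ExonIntronSummary:
    gene_id: str
    per_exon_mean: list[float]
    per_intron_mean: list[float]
    exon_intron_ratio: Optional[float]  # None when not applicable


def _usable(rec: pysam.AlignedSegment) -> bool:
    return not (
        rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate
    )


def extract_depth(
    alignments: str | Path, region: GenomicInterval
) -> np.ndarray:
    """Per-position depth over ``region``, zeros included.

    Counts aligned bases of primary, non-duplicate reads (gapped alignments
    contribute only their aligned blocks, so spliced or clipped portions add
    no depth). Requires an indexed alignment file.
    """
    depth = np.zeros(region.length, dtype=np.int64)
    with pysam.AlignmentFile(str(alignments)) as af:
        if region.chrom not in af.references:
            raise ValueError(
                f"chromosome {region.chrom!r} absent from {alignments}"
            )
        for rec in af.fetch(region.chrom, region.start, region.end):
            if not _usable(rec):
                continue
            for bs, be in rec.get_blocks():
                lo = max(bs, region.start) - region.start
                hi = min(be, region.end) - region.start
                if hi > lo:
                    depth[lo:hi] += 1
    return depth


def chromosome_mean_depth(alignments: str | Path, chrom: str) -> float:
    """Mean depth over an entire reference sequence (zeros included)."""
    with pysam.AlignmentFile(str(alignments)) as af:
        if chrom not in af.references:
            raise ValueError(f"chromosome {chrom!r} absent from {alignments}")
        length = af.get_reference_length(chrom)
        total = 0
        for rec in af.fetch(chrom):
            if not _usable(rec):
                continue
            for bs, be in rec.get_blocks():
                total += min(be, length) - max(bs, 0)
    return total / length


def pick_normalization_chrom(alignments: str | Path) -> str:
    """Default normalisation chromosome: the largest reference sequence
    (with human data this is chr1, the conventional choice)."""
    with pysam.AlignmentFile(str(alignments)) as af:
        pairs = list(zip(af.references, af.lengths))
    return max(pairs, key=lambda p: (p[1], p[0]))[0]


def normalize_depth(raw_depth: np.ndarray, reference_mean: float) -> np.ndarray:
    """Diploid-scale normalisation: ``2 · raw / reference_mean``.

    A position at the genome-average depth maps to 2.0 (two copies).
    """
    if reference_mean <= 0:
        raise ValueError("reference_mean must be > 0")
    return 2.0 * np.asarray(raw_depth, dtype=float) / reference_mean


def summarize_exon_intron(
    profile: DepthProfile, transcript: TranscriptModel
) -> ExonIntronSummary:
    """Per-exon and per-intron mean normalised depth and their ratio.

    The ratio is the unweighted mean of exon means over the unweighted mean
    of intron means (each feature counts equally regardless of length); it
    is not applicable for single-exon transcripts.
    """
    if profile.norm_depth is None:
        raise ValueError("profile has no normalised depth")
    if not profile.span.contains(transcript.span):
        raise ValueError("profile does not cover the transcript span")

    def feature_mean(iv: GenomicInterval) -> float:
        lo = iv.start - profile.span.start
        hi = iv.end - profile.span.start
        return float(np.mean(profile.norm_depth[lo:hi]))

    exon_means = [feature_mean(e) for e in transcript.exons]
    intron_means = [feature_mean(i) for i in derive_introns(transcript)]
    if len(transcript.exons) < 2 or np.mean(intron_means) == 0:
        ratio = None
    else:
        ratio = float(np.mean(exon_means) / np.mean(intron_means))
    return ExonIntronSummary(profile.gene_id, exon_means, intron_means, ratio)


def cohort_ratio_histogram(
    summaries: Iterable[ExonIntronSummary], bin_width: float = 0.1
) -> pd.DataFrame:
    """Histogram of exon/intron ratios across (sample, gene) summaries."""
    ratios = [s.exon_intron_ratio for s in summaries if s.exon_intron_ratio is not None]
    if not ratios:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    lo = np.floor(min(ratios) / bin_width) * bin_width
    hi = np.ceil(max(ratios) / bin_width) * bin_width + bin_width / 2
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(ratios, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def average_profiles(profiles: Sequence[DepthProfile]) -> np.ndarray:
    """Positionwise mean of normalised depth across individuals sharing one
    gene (carrier-group or control-group average profile)."""
    if not profiles:
        raise ValueError("no profiles to average")
    spans = {(p.span.chrom, p.span.start, p.span.end) for p in profiles}
    if len(spans) != 1:
        raise ValueError("profiles cover different spans")
    return np.mean([p.norm_depth for p in profiles], axis=0)
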