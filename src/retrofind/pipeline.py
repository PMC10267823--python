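"""End-to-end orchestration: extract → call → position → coverage → popstats.

`run_pipeline` chains the per-sample stages over a cohort described by a
RunConfig and writes one results directory. Every stage reads only files and
writes only new files, so stages are individually re-runnable and nothing
mutates its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from . import candidates as cand
from . import coverage as cov
from . import discordant_reads as dr
from . import enrichment as enr
from . import positioning as pos
from .genome_model import load_gene_models, read_bed

log = logging.getLogger(__name__)


@dataclass
class SampleInput:
    sample_id: str
    bam: Path
    vcf: Optional[Path] = None
    population: str = "cohort"


@dataclass
class RunConfig:
    """All inputs and tunable thresholds of a pipeline run.

    Threshold defaults are the method's operating point: candidates need
    more than 20 supporting reads and at least 3X transcript coverage;
    insert sites within 500 bp collapse; breakends count as near-terminus
    within 1 kb; the enrichment null uses 10,000 Monte Carlo draws.
    """

    annotation: Path
    samples: list[SampleInput]
    out_dir: Path
    min_insert_override: Optional[int] = None
    min_mapq: int = dr.DEFAULT_MIN_MAPQ
    min_reads: int = cand.DEFAULT_MIN_READS
    min_coverage: float = cand.DEFAULT_MIN_COVERAGE
    terminus_window: int = pos.DEFAULT_TERMINUS_WINDOW
    max_gap: int = pos.DEFAULT_MAX_GAP
    iterations: int = enr.DEFAULT_ITERATIONS
    seed: int = 1
    norm_chrom: Optional[str] = None
    feature_tracks: list[Path] = field(default_factory=list)
    chrom_sizes: Optional[Path] = None

    def __post_init__(self) -> None:
        for name in ("min_mapq", "min_reads", "terminus_window", "max_gap",
                     "iterations"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.min_coverage < 0:
            raise ValueError("min_coverage must be non-negative")

    def config_hash(self) -> str:
        payload = {
            k: str(v) for k, v in self.__dict__.items() if k != "samples"
        }
        payload["samples"] = [s.sample_id for s in self.samples]
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class RunResult:
    out_dir: Path
    cohort: pd.DataFrame
    clusters: dict[tuple[str, str], list[pos.InsertSiteCluster]]
    positioned_fraction: Optional[float]
    summaries: list[enr.PopulationSummary]
    enrichment: list[enr.EnrichmentResult]


def run_pipeline(config: RunConfig) -> RunResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = [
        f"retrofind {__version__}",
        f"config_hash {config.config_hash()}",
        f"seed {config.seed}",
    ]
    genes = load_gene_models(config.annotation)

    candidates_by_sample = {}
    populations = {}
    clusters: dict[tuple[str, str], list[pos.InsertSiteCluster]] = {}
    all_clusters: list[pos.InsertSiteCluster] = []
    ratio_rows = []

    for sample in config.samples:
        populations[sample.sample_id] = sample.population
        stats = None
        if config.min_insert_override is None:
            stats = dr.estimate_library_stats(sample.bam)
            if stats.warning:
                log.warning("%s: %s", sample.sample_id, stats.warning)
        pairs = dr.extract_discordant_pairs(
            sample.bam, genes, stats=stats,
            min_insert_override=config.min_insert_override,
            min_mapq=config.min_mapq,
        )
        dr.write_pairs_tsv(
            pairs, out_dir / f"{sample.sample_id}.pairs.tsv", stamp
        )
        support = cand.quantify_support(pairs, genes)
        sample_cands = cand.call_candidates(
            support, genes, sample.sample_id,
            min_reads=config.min_reads, min_coverage=config.min_coverage,
        )
        candidates_by_sample[sample.sample_id] = sample_cands

        calls = (
            pos.load_breakpoint_calls(sample.vcf, sample.sample_id)
            if sample.vcf else []
        )
        norm_chrom = config.norm_chrom or cov.pick_normalization_chrom(sample.bam)
        ref_mean = cov.chromosome_mean_depth(sample.bam, norm_chrom)
        for c in sample_cands:
            gene = genes[c.gene_id]
            evidence = pos.find_insert_breakpoints(
                calls, gene, config.terminus_window
            )
            cls = pos.cluster_insert_sites(
                evidence, gene_id=c.gene_id, max_gap=config.max_gap
            )
            clusters[(c.sample_id, c.gene_id)] = cls
            all_clusters.extend(cls)

            raw = cov.extract_depth(sample.bam, gene.span)
            profile = cov.DepthProfile(
                c.gene_id, gene.span, raw, cov.normalize_depth(raw, ref_mean)
            )
            summary = cov.summarize_exon_intron(
                profile, gene.transcript(c.transcript_id)
            )
            ratio_rows.append(
                {
                    "sample_id": c.sample_id,
                    "gene_id": c.gene_id,
                    "exon_intron_ratio": summary.exon_intron_ratio,
                }
            )

    cohort = cand.merge_cohort(candidates_by_sample, populations)
    cohort.to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
    pos.write_clusters_bed(all_clusters, out_dir / "insert_sites.bed")
    pd.DataFrame(
        ratio_rows, columns=["sample_id", "gene_id", "exon_intron_ratio"]
    ).to_csv(out_dir / "exon_intron_ratios.tsv", sep="\t", index=False)

    frac = pos.positioned_fraction(
        [(r.sample_id, r.gene_id) for cs in candidates_by_sample.values()
         for r in cs],
        clusters,
    )
    manifest = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in config.samples],
            "population": [s.population for s in config.samples],
        }
    )
    summaries = enr.summarize_populations(cohort, manifest)
    enr.write_population_tsv(summaries, out_dir / "population_summary.tsv")

    results: list[enr.EnrichmentResult] = []
    if config.feature_tracks and config.chrom_sizes and all_clusters:
        layout = enr.GenomeLayout.from_chrom_sizes(config.chrom_sizes)
        tracks = [read_bed(p) for p in config.feature_tracks]
        sites = [(c.chrom, c.position) for c in all_clusters]
        results = enr.run_enrichment(
            sites, tracks, layout, config.iterations, seed=config.seed
        )
        enr.write_enrichment_tsv(results, out_dir / "enrichment.tsv", stamp)

    with open(out_dir / "run_info.json", "w") as fh:
        json.dump(
            {
                "version": __version__,
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "positioned_fraction": frac,
            },
            fh, indent=1,
        )
        fh.write("\n")
    return RunResult(out_dir, cohort, clusters, frac, summaries, results)
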