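"""Shared fixtures: hand-built toy gene models and simulated cohorts.

The simulated cohorts are session-scoped because generating alignments is
the expensive part of the suite; tests must not mutate their files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pysam
import pytest

from retrofind.genome_model import (
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    load_gene_models,
)
from retrofind.simulate import make_cohort_config, simulate_cohort


@pytest.fixture
def toy_transcript() -> TranscriptModel:
    """4 exons of 100 bp separated by 200 bp introns on chrA:[1000,2200)."""
    exons = tuple(
        GenomicInterval("chrA", 1000 + i * 300, 1100 + i * 300, "+")
        for i in range(4)
    )
    return TranscriptModel("TX1", exons)


@pytest.fixture
def toy_gene(toy_transcript) -> GeneModel:
    return GeneModel(
        "G1", "G1", GenomicInterval("chrA", 1000, 2200, "+"), (toy_transcript,)
    )


@pytest.fixture
def two_gene_models() -> dict[str, GeneModel]:
    """Two genes on one chromosome for pair-classification tests."""
    def make(gene_id, start):
        exons = tuple(
            GenomicInterval("chrA", start + i * 1300, start + i * 1300 + 300, "+")
            for i in range(3)
        )
        tx = TranscriptModel(f"{gene_id}.t1", exons)
        span = GenomicInterval("chrA", start, exons[-1].end, "+")
        return GeneModel(gene_id, gene_id, span, (tx,))

    return {g.gene_id: g for g in (make("GA", 2000), make("GB", 10000))}


def write_toy_bam(path: Path, records: list[dict], chroms=(("chrA", 50_000),)):
    """Write an (unindexed, queryable-by-stream) BAM from record dicts."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": ln} for c, ln in chroms],
        }
    )
    with pysam.AlignmentFile(str(path), "wb", header=header) as bf:
        for rec in records:
            a = pysam.AlignedSegment(header)
            a.query_name = rec["name"]
            a.flag = rec.get("flag", 0x1)
            a.reference_id = rec.get("tid", 0)
            a.reference_start = rec["pos"]
            a.mapping_quality = rec.get("mapq", 60)
            a.cigarstring = rec.get("cigar", f"{rec.get('length', 100)}M")
            a.next_reference_id = rec.get("mtid", rec.get("tid", 0))
            a.next_reference_start = rec.get("mpos", rec["pos"])
            a.template_length = rec.get("tlen", 0)
            bf.write(a)
    return path


class Cohort:
    """Bundle of a simulated cohort and its parsed truth."""

    def __init__(self, config, sim):
        self.config = config
        self.sim = sim
        self.genes = load_gene_models(sim.reference.gtf_path)
        with open(sim.manifest_path) as fh:
            self.truth = json.load(fh)

    @property
    def carriers(self):
        return {
            s: rcs for s, rcs in self.truth["samples"].items() if rcs
        }


@pytest.fixture(scope="session")
def cohort30(tmp_path_factory) -> Cohort:
    """20 samples, 10 heterozygous carriers, 30X: the detection cohort."""
    cfg = make_cohort_config(n_samples=20, n_carriers=10, seed=101)
    sim = simulate_cohort(cfg, tmp_path_factory.mktemp("cohort30"))
    return Cohort(cfg, sim)


@pytest.fixture(scope="session")
def cohort60(tmp_path_factory) -> Cohort:
    """16 samples at 60X: 6 one-copy and 6 two-copy carriers, 4 controls —
    the copy-ratio calibration cohort."""
    cfg = make_cohort_config(
        n_samples=16, n_carriers=12, seed=202, copy_numbers=[1, 2],
        target_coverage=60.0,
    )
    sim = simulate_cohort(cfg, tmp_path_factory.mktemp("cohort60"))
    return Cohort(cfg, sim)


@pytest.fixture(scope="session")
def mini_cohort(tmp_path_factory) -> Cohort:
    """4 samples (one het carrier, one two-copy carrier), 30X: cheap fixture
    for module-level tests."""
    cfg = make_cohort_config(
        n_samples=4, n_carriers=2, seed=7, copy_numbers=[1, 2]
    )
    sim = simulate_cohort(cfg, tmp_path_factory.mktemp("mini"))
    return Cohort(cfg, sim)
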