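"""Library-stats estimation and exon-discordant pair extraction."""

import random

import pytest

from retrofind.discordant_reads import (
    DiscordantPair,
    LibraryStats,
    Mate,
    AlignedPair,
    discordance_threshold,
    estimate_library_stats,
    extract_discordant_pairs,
    read_pairs_tsv,
    write_pairs_tsv,
)
from retrofind.genome_model import GenomicInterval, assign_to_exon

from conftest import write_toy_bam

READ_LEN = 100


def make_pair_records(name, p1, p2, mapq=60, tlen=None, proper=True):
    """Two BAM records for a forward/reverse pair at p1 < p2."""
    t = tlen if tlen is not None else p2 + READ_LEN - p1
    base = 0x1 | (0x2 if proper else 0)
    return [
        {"name": name, "flag": base | 0x20 | 0x40, "pos": p1, "mpos": p2,
         "tlen": t, "mapq": mapq, "length": READ_LEN},
        {"name": name, "flag": base | 0x10 | 0x80, "pos": p2, "mpos": p1,
         "tlen": -t, "mapq": mapq, "length": READ_LEN},
    ]


def naive_extract(pairs, genes, threshold, min_mapq):
    """Literal application of the three discordance conditions."""
    hits = set()
    for name, p1, p2, mapq, tlen in pairs:
        iv1 = GenomicInterval("chrA", p1, p1 + READ_LEN)
        iv2 = GenomicInterval("chrA", p2, p2 + READ_LEN)
        if tlen <= threshold or mapq < min_mapq:
            continue
        for gene in genes.values():
            if not (gene.span.contains(iv1) and gene.span.contains(iv2)):
                continue
            for tx in gene.transcripts:
                i1 = assign_to_exon(iv1, tx)
                i2 = assign_to_exon(iv2, tx)
                if i1 is not None and i2 is not None and i1 != i2:
                    hits.add((name, gene.gene_id))
                    break
    return hits


class TestEstimateLibraryStats:
    def test_constant_template_lengths(self, tmp_path):
        records = []
        for i in range(1200):
            records.extend(make_pair_records(f"r{i}", 1000 + i, 1200 + i, tlen=300))
        bam = write_toy_bam(tmp_path / "t.bam", records)
        stats = estimate_library_stats(bam)
        assert stats.mean_insert == 300
        assert stats.sd_insert == 0
        assert stats.warning is None

    def test_small_sample_attaches_warning(self, tmp_path):
        records = []
        for i in range(10):
            records.extend(make_pair_records(f"r{i}", 1000, 1200, tlen=300))
        stats = estimate_library_stats(write_toy_bam(tmp_path / "t.bam", records))
        assert stats.n_sampled == 10
        assert stats.warning is not None

    def test_no_proper_pairs_is_an_error(self, tmp_path):
        bam = write_toy_bam(
            tmp_path / "t.bam",
            make_pair_records("r0", 1000, 1200, proper=False),
        )
        with pytest.raises(ValueError, match="threshold"):
            estimate_library_stats(bam)

    def test_simulated_library_recovered(self, mini_cohort):
        cfg = mini_cohort.config
        stats = estimate_library_stats(mini_cohort.sim.bam_paths["S002"])
        se_mean = cfg.insert_sd / stats.n_sampled ** 0.5
        assert abs(stats.mean_insert - cfg.insert_mean) < 3 * se_mean
        se_sd = cfg.insert_sd / (2 * stats.n_sampled) ** 0.5
        assert abs(stats.sd_insert - cfg.insert_sd) < 3 * se_sd


def test_threshold_is_floor_or_three_sigma():
    assert discordance_threshold(LibraryStats(400, 50, 5000)) == 1000
    assert discordance_threshold(LibraryStats(800, 200, 5000)) == 1400
    assert discordance_threshold(LibraryStats(400, 50, 5000), 250) == 250


class TestExtraction:
    def pair_specs(self, genes):
        """Enumerated pair configurations on the two-gene toy genome.

        GA exons: [2000,2300) [3300,3600) [4600,4900); GB shifted to 10000.
        """
        return [
            # exons 0 and 2, big template: the retrocopy signature
            ("keep_far_exons", 2100, 4700, 60, 2700),
            # both mates in exon 0
            ("same_exon", 2050, 2150, 60, 2000),
            # exon 0 / exon 1 but template below the 1000 threshold
            ("short_template", 2150, 3350, 60, 900),
            # template exactly at the threshold: strict inequality
            ("at_threshold", 2150, 3350, 60, 1000),
            # one mate intronic
            ("intron_mate", 2100, 2500, 60, 1500),
            # mates in different genes
            ("cross_gene", 2100, 10100, 60, 8100),
            # low mapping quality
            ("low_mapq", 2100, 4700, 5, 2700),
            # exon 0 / exon 1 above threshold
            ("keep_adjacent_exons", 2100, 3400, 60, 1400),
        ]

    def build_bam(self, tmp_path, genes, specs):
        records = []
        for name, p1, p2, mapq, tlen in specs:
            records.extend(make_pair_records(name, p1, p2, mapq=mapq, tlen=tlen))
        return write_toy_bam(tmp_path / "pairs.bam", records)

    def test_enumerated_configurations_match_oracle(self, tmp_path, two_gene_models):
        specs = self.pair_specs(two_gene_models)
        bam = self.build_bam(tmp_path, two_gene_models, specs)
        found = {
            (d.pair.read_id, d.gene_id)
            for d in extract_discordant_pairs(
                bam, two_gene_models, min_insert_override=1000
            )
        }
        assert found == naive_extract(specs, two_gene_models, 1000, 10)
        assert found == {("keep_far_exons", "GA"), ("keep_adjacent_exons", "GA")}

    def test_random_pairs_match_oracle(self, tmp_path, two_gene_models):
        rnd = random.Random(7)
        specs = []
        for i in range(400):
            p1 = rnd.randint(1500, 11500)
            p2 = p1 + rnd.randint(0, 3500)
            if p2 + READ_LEN >= 50_000:
                continue
            specs.append(
                (f"rnd{i}", p1, p2, rnd.choice([0, 5, 10, 60]),
                 rnd.randint(100, 4000))
            )
        bam = self.build_bam(tmp_path, two_gene_models, specs)
        found = {
            (d.pair.read_id, d.gene_id)
            for d in extract_discordant_pairs(
                bam, two_gene_models, min_insert_override=1000
            )
        }
        assert found == naive_extract(specs, two_gene_models, 1000, 10)

    def test_deterministic_and_monotone_in_threshold(self, tmp_path, two_gene_models):
        specs = self.pair_specs(two_gene_models)
        bam = self.build_bam(tmp_path, two_gene_models, specs)
        first = extract_discordant_pairs(bam, two_gene_models, min_insert_override=1000)
        second = extract_discordant_pairs(bam, two_gene_models, min_insert_override=1000)
        assert first == second
        stricter = extract_discordant_pairs(
            bam, two_gene_models, min_insert_override=2000
        )
        assert {d.pair.read_id for d in stricter} <= {d.pair.read_id for d in first}

    def test_secondary_and_duplicate_records_ignored(self, tmp_path, two_gene_models):
        specs = [("keep_far_exons", 2100, 4700, 60, 2700)]
        records = []
        for rec in make_pair_records(*specs[0][:3], tlen=specs[0][4]):
            records.append(dict(rec, flag=rec["flag"] | 0x400))  # duplicates
        bam = write_toy_bam(tmp_path / "d.bam", records)
        assert extract_discordant_pairs(bam, two_gene_models, min_insert_override=1000) == []


def test_pairs_tsv_round_trip(tmp_path):
    m1 = Mate.from_interval(GenomicInterval("chrA", 2100, 2200))
    m2 = Mate.from_interval(GenomicInterval("chrA", 4700, 4800))
    d = DiscordantPair(
        pair=AlignedPair("r1", m1, m2, 2700),
        gene_id="GA", transcript_id="GA.t1",
        exon_index_1=0, exon_index_2=2, exon_bases_1=100, exon_bases_2=100,
    )
    path = tmp_path / "pairs.tsv"
    write_pairs_tsv([d], path, header_lines=["test"])
    assert read_pairs_tsv(path) == [d]


def test_same_exon_assignment_is_invalid():
    m = Mate.from_interval(GenomicInterval("chrA", 2100, 2200))
    with pytest.raises(ValueError):
        DiscordantPair(
            pair=AlignedPair("r", m, m, 2000),
            gene_id="GA", transcript_id="t",
            exon_index_1=1, exon_index_2=1, exon_bases_1=100, exon_bases_2=100,
        )
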