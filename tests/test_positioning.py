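"""Breakpoint filtering, insert-site clustering, deletion-miscall counting."""

import random

import pytest

from retrofind.genome_model import GeneModel, GenomicInterval, TranscriptModel
from retrofind.positioning import (
    BreakpointCall,
    InsertEvidence,
    cluster_insert_sites,
    count_deletion_calls,
    find_insert_breakpoints,
    load_breakpoint_calls,
    positioned_fraction,
)


@pytest.fixture
def gene():
    """GENE on chrA:[10000, 14200): 4 exons of 300 bp, 1 kb introns."""
    exons = tuple(
        GenomicInterval("chrA", 10000 + i * 1300, 10300 + i * 1300, "+")
        for i in range(4)
    )
    tx = TranscriptModel("T", exons)
    return GeneModel("G", "G", GenomicInterval("chrA", 10000, 14200, "+"), (tx,))


def naive_insert_evidence(calls, gene, window):
    """Literal application of the near-terminus and distance clauses."""
    out = set()
    for call in calls:
        for ca, pa, cb, pb in (
            (call.chrom_a, call.pos_a, call.chrom_b, call.pos_b),
            (call.chrom_b, call.pos_b, call.chrom_a, call.pos_a),
        ):
            near = ca == gene.chrom and (
                abs(pa - gene.span.start) <= window
                or abs(pa - gene.span.end) <= window
            )
            far = cb != ca or abs(pb - pa) >= gene.gene_length
            if near and far:
                out.add((cb, pb))
    return out


class TestFindInsertBreakpoints:
    def test_trans_partner_near_start(self, gene):
        call = BreakpointCall("chrA", 9800, "chrB", 5000, "BND")
        assert find_insert_breakpoints([call], gene) == [
            InsertEvidence("chrB", 5000)
        ]

    def test_intragenic_deletion_is_not_evidence(self, gene):
        call = BreakpointCall("chrA", 10350, "chrA", 11500, "DEL")
        assert find_insert_breakpoints([call], gene) == []

    def test_breakend_outside_window_is_not_evidence(self, gene):
        call = BreakpointCall("chrA", 5000, "chrB", 100, "BND")
        assert find_insert_breakpoints([call], gene, terminus_window=1000) == []

    def test_same_chrom_far_partner_is_evidence(self, gene):
        call = BreakpointCall("chrA", 14500, "chrA", 40000, "BND")
        assert find_insert_breakpoints([call], gene) == [
            InsertEvidence("chrA", 40000)
        ]

    def test_random_calls_match_oracle(self, gene):
        rnd = random.Random(11)
        calls = []
        for _ in range(200):
            if rnd.random() < 0.5:
                a = rnd.randint(0, 30000)
                calls.append(
                    BreakpointCall("chrA", a, "chrA", a + rnd.randint(1, 20000), "DEL")
                )
            else:
                calls.append(
                    BreakpointCall(
                        rnd.choice(["chrA", "chrB"]), rnd.randint(0, 30000),
                        rnd.choice(["chrA", "chrB"]), rnd.randint(0, 30000), "BND",
                    )
                )
        got = {
            (ev.chrom, ev.position)
            for ev in find_insert_breakpoints(calls, gene, terminus_window=1000)
        }
        assert got == naive_insert_evidence(calls, gene, 1000)


def naive_clusters(positions, max_gap):
    """Transitive closure of the within-max_gap relation (per chromosome)."""
    groups = []
    for chrom, pos in positions:
        merged = [g for g in groups
                  if g[0] == chrom and any(abs(p - pos) <= max_gap for p in g[1])]
        for g in merged:
            groups.remove(g)
        groups.append((chrom, sorted(p for _, ps in merged for p in ps) + [pos]))
    return {(c, tuple(sorted(ps))) for c, ps in groups}


class TestClusterInsertSites:
    def test_gap_above_threshold_stays_unique(self):
        clusters = cluster_insert_sites([("c", 100), ("c", 700)], max_gap=500)
        assert len(clusters) == 2

    def test_gap_at_threshold_collapses_to_lower_median(self):
        (cluster,) = cluster_insert_sites([("c", 100), ("c", 600)], max_gap=500)
        assert cluster.members == [100, 600]
        assert cluster.position == 100  # lower of the two middles

    def test_chained_positions_merge_transitively(self):
        (cluster,) = cluster_insert_sites([("c", 0), ("c", 400), ("c", 800)])
        assert cluster.members == [0, 400, 800]
        assert cluster.position == 400

    def test_input_order_irrelevant(self):
        rnd = random.Random(3)
        positions = [("c", rnd.randint(0, 10000)) for _ in range(30)]
        ref = cluster_insert_sites(positions)
        for _ in range(5):
            rnd.shuffle(positions)
            got = cluster_insert_sites(positions)
            assert [(c.chrom, c.position, sorted(c.members)) for c in got] == [
                (c.chrom, c.position, sorted(c.members)) for c in ref
            ]

    def test_matches_transitive_closure_oracle(self):
        rnd = random.Random(5)
        for _ in range(300):
            n = rnd.randint(1, 20)
            positions = [
                (rnd.choice(["c1", "c2"]), rnd.randint(0, 5000)) for _ in range(n)
            ]
            got = {
                (c.chrom, tuple(sorted(c.members)))
                for c in cluster_insert_sites(positions)
            }
            assert got == naive_clusters(positions, 500)

    def test_monotone_in_max_gap(self):
        rnd = random.Random(9)
        positions = [("c", rnd.randint(0, 20000)) for _ in range(50)]
        n_prev = None
        for gap in (100, 500, 1000, 5000):
            n = len(cluster_insert_sites(positions, max_gap=gap))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_samples_counted_once_per_cluster(self):
        evidence = [
            InsertEvidence("c", 100, "s1"),
            InsertEvidence("c", 150, "s1"),
            InsertEvidence("c", 200, "s2"),
        ]
        (cluster,) = cluster_insert_sites(evidence)
        assert cluster.sample_count == 2


class TestDeletionCounts:
    def test_intronic_and_exonic_split(self, gene):
        calls = [
            BreakpointCall("chrA", 10350, "chrA", 11200, "DEL"),
            BreakpointCall("chrA", 11650, "chrA", 12500, "DEL"),
            BreakpointCall("chrA", 12950, "chrA", 13800, "DEL"),
            BreakpointCall("chrA", 10250, "chrA", 11200, "DEL"),  # clips exon 0
        ]
        assert count_deletion_calls(calls, gene) == (4, 1)
        assert [c.overlaps_exon for c in calls] == [False, False, False, True]

    def test_no_deletions(self, gene):
        bnd = BreakpointCall("chrA", 9800, "chrB", 5000, "BND")
        assert count_deletion_calls([bnd], gene) == (0, 0)

    def test_deletions_outside_gene_not_counted(self, gene):
        calls = [BreakpointCall("chrA", 20000, "chrA", 21000, "DEL")]
        assert count_deletion_calls(calls, gene) == (0, 0)


def test_positioned_fraction():
    clusters = {("s1", "g"): [object()], ("s2", "g"): []}
    keys = [("s1", "g"), ("s2", "g"), ("s3", "g"), ("s4", "g")]
    clusters[("s4", "g")] = [object()]
    clusters[("s3", "g")] = [object()]
    assert positioned_fraction(keys, clusters) == 0.75
    assert positioned_fraction([], clusters) is None


class TestVcfParsing:
    def test_simulator_vcf_parses_and_matches_truth(self, mini_cohort):
        sample = next(iter(mini_cohort.carriers))
        rc = mini_cohort.carriers[sample][0]
        calls = load_breakpoint_calls(mini_cohort.sim.vcf_paths[sample], sample)
        dels = [c for c in calls if c.sv_type == "DEL"]
        bnds = [c for c in calls if c.sv_type == "BND"]
        gene_info = mini_cohort.truth["genes"][rc["parent_gene"]]
        n_introns = gene_info["n_exons"] - 1
        assert len(dels) == n_introns + mini_cohort.config.n_decoy_dels
        # each junction is reported from both sides
        assert len(bnds) == 4
        partners = {
            c.pos_b for c in bnds if c.chrom_b == rc["insert_chrom"]
        }
        assert partners
        for p in partners:
            assert abs(p - rc["insert_pos"]) <= mini_cohort.config.tsd_length

    def test_noncarrier_vcf_has_only_decoys(self, mini_cohort):
        calls = load_breakpoint_calls(mini_cohort.sim.vcf_paths["S003"], "S003")
        assert len(calls) == mini_cohort.config.n_decoy_dels
        assert all(c.sv_type == "DEL" for c in calls)
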