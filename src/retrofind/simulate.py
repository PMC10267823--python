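"""Self-contained synthetic WGS datasets with planted retrocopies.

The generator builds a toy multi-gene genome and, per diploid individual,
paired-end alignments in which every planted retrocopy leaves exactly the
footprint the detection pipeline looks for:

* background pairs are drawn uniformly at the target coverage and mapped
  where they originate, with Normal(insert_mean, insert_sd) template lengths;
* retrocopy pairs are drawn from the intron-less retrocopy sequence (spliced
  exons + poly-A tail) at ``copy_number · target_coverage / 2`` — one copy is
  a heterozygous insertion on a diploid background — and emitted as mapping
  back onto the parent gene's exons. A mate spanning an exon-exon junction
  of the retrocopy maps as a spliced alignment across the intron, and the
  pair's genomic template length is inflated by the skipped introns: the
  oversized-insert signature. Poly-A-derived mates have no reference home
  and are emitted as placed-unmapped records;
* the SV VCF contains the two informative breakends linking each parent
  gene's termini to the true insertion site, one spurious deletion call per
  parent-gene intron (the miscall signature of short-read SV callers), and
  configurable random decoy deletions elsewhere.

Everything is deterministic for a fixed config seed; a truth manifest
records what was planted so tests can compare pipeline output to ground
truth.

Simplifications relative to real data: reads are placed, not re-aligned, so
there is no mapping ambiguity or loss; junction mates are spliced rather
than soft-clipped; qualities are constant and there is no SNP/indel or
repeat background.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam

from .genome_model import GeneModel, GenomicInterval, TranscriptModel, write_gtf

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Retrocopy:
    """One planted retrocopy: which gene, where it landed, how many copies."""

    parent_gene: str
    insert_chrom: str
    insert_pos: int
    copy_number: int = 1

    def __post_init__(self) -> None:
        if self.copy_number not in (1, 2):
            raise ConfigError("copy_number must be 1 or 2")


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror a PCR-free 30X short-read WGS experiment (120 bp
    paired-end reads, ~400±50 bp inserts) on a toy two-chromosome genome of
    five 4-exon genes (300 bp exons, 1 kb introns).
    """

    n_chromosomes: int = 2
    chrom_length: int = 100_000
    n_genes: int = 5
    exons_per_gene: int = 4
    exon_length: int = 300
    intron_length: int = 1000
    read_length: int = 120
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    target_coverage: float = 30.0
    polyA_length: int = 150
    tsd_length: int = 10
    error_rate: float = 0.001
    n_decoy_dels: int = 3
    exonic_miscall_prob: float = 0.0
    samples: tuple[str, ...] = ()
    carrier_table: dict[str, list[Retrocopy]] = field(default_factory=dict)
    seed: int = 1

    def __post_init__(self) -> None:
        for name, value in (
            ("chrom_length", self.chrom_length), ("exon_length", self.exon_length),
            ("intron_length", self.intron_length), ("read_length", self.read_length),
            ("polyA_length", self.polyA_length),
        ):
            if value <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.insert_mean <= 2 * self.read_length:
            raise ConfigError("insert_mean must exceed 2 · read_length")
        if not self.samples:
            self.samples = tuple(sorted(self.carrier_table))
        missing = set(self.carrier_table) - set(self.samples)
        if missing:
            raise ConfigError(f"carriers not in sample list: {sorted(missing)}")

    @property
    def gene_span_length(self) -> int:
        return (
            self.exons_per_gene * self.exon_length
            + (self.exons_per_gene - 1) * self.intron_length
        )

    @property
    def transcript_length(self) -> int:
        return self.exons_per_gene * self.exon_length


@dataclass
class SimulatedReference:
    config: SimConfig
    sequences: dict[str, str]
    genes: dict[str, GeneModel]
    fasta_path: Path
    gtf_path: Path
    chrom_sizes_path: Path

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)


def _sample_rng(config: SimConfig, sample_id: str, tag: str) -> np.random.Generator:
    return np.random.default_rng(
        [config.seed, zlib.crc32(sample_id.encode()), zlib.crc32(tag.encode())]
    )


_GENE_MARGIN = 3000
_GENE_GAP = 3000


def generate_reference(config: SimConfig, out_dir: str | Path) -> SimulatedReference:
    """Build the toy genome: FASTA + GTF + chrom-sizes, all seeded."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, zlib.crc32(b"reference")])

    sequences: dict[str, str] = {}
    for i in range(config.n_chromosomes):
        seq = rng.choice(_BASES, size=config.chrom_length)
        sequences[f"chr{i + 1}"] = seq.tobytes().decode()

    per_chrom_capacity = (
        config.chrom_length - 2 * _GENE_MARGIN + _GENE_GAP
    ) // (config.gene_span_length + _GENE_GAP)
    if per_chrom_capacity * config.n_chromosomes < config.n_genes:
        raise ConfigError(
            f"{config.n_genes} genes of {config.gene_span_length} bp do not fit "
            f"on {config.n_chromosomes} × {config.chrom_length} bp chromosomes"
        )

    genes: dict[str, GeneModel] = {}
    placed: dict[str, int] = {c: 0 for c in sequences}
    chroms = list(sequences)
    for g in range(config.n_genes):
        chrom = chroms[g % len(chroms)]
        slot = placed[chrom]
        placed[chrom] += 1
        start = _GENE_MARGIN + slot * (config.gene_span_length + _GENE_GAP)
        exons = []
        for e in range(config.exons_per_gene):
            es = start + e * (config.exon_length + config.intron_length)
            exons.append(
                GenomicInterval(chrom, es, es + config.exon_length, "+")
            )
        gene_id = f"GENE{g + 1}"
        tx = TranscriptModel(f"{gene_id}.t1", tuple(exons))
        genes[gene_id] = GeneModel(
            gene_id, gene_id,
            GenomicInterval(chrom, start, start + config.gene_span_length, "+"),
            (tx,),
        )

    fasta_path = out_dir / "reference.fa"
    with open(fasta_path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    pysam.faidx(str(fasta_path))

    gtf_path = out_dir / "annotation.gtf"
    write_gtf(genes.values(), gtf_path)

    sizes_path = out_dir / "chrom.sizes"
    with open(sizes_path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f"{chrom}\t{len(seq)}\n")

    return SimulatedReference(config, sequences, genes, fasta_path, gtf_path, sizes_path)


def _transcript_blocks(
    tx: TranscriptModel, lo: int, hi: int
) -> list[tuple[int, int]]:
    """Project transcript-coordinate range [lo, hi) onto genome blocks."""
    blocks = []
    cum = 0
    for exon in tx.exons:
        s, e = max(lo, cum), min(hi, cum + exon.length)
        if e > s:
            blocks.append((exon.start + s - cum, exon.start + e - cum))
        cum += exon.length
    return blocks


def _blocks_cigar(
    blocks: Sequence[tuple[int, int]], soft_right: int, soft_left: int = 0
) -> str:
    parts = [f"{soft_left}S"] if soft_left else []
    parts.append(f"{blocks[0][1] - blocks[0][0]}M")
    for (ps, pe), (ns, ne) in zip(blocks, blocks[1:]):
        parts.append(f"{ns - pe}N{ne - ns}M")
    if soft_right:
        parts.append(f"{soft_right}S")
    return "".join(parts)


def _flank(seq: str, lo: int, hi: int) -> str:
    """Reference slice padded with N where it runs off the chromosome."""
    return (
        "N" * max(0, -lo)
        + seq[max(0, lo):max(0, min(hi, len(seq)))]
        + "N" * max(0, hi - len(seq))
    )


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    arr = bytearray(seq, "ascii")
    for pos in rng.integers(0, len(arr), size=n_err):
        arr[pos] = ord("ACGT"[rng.integers(0, 4)])
    return arr.decode()


def simulate_individual(
    config: SimConfig,
    reference: SimulatedReference,
    sample_id: str,
    out_dir: str | Path,
) -> Path:
    """Emit one individual's coordinate-sorted, indexed BAM."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _sample_rng(config, sample_id, "reads")
    rl = config.read_length
    proper_cut = config.insert_mean + 4 * config.insert_sd

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": c, "LN": len(s)} for c, s in reference.sequences.items()
            ],
            "RG": [{"ID": sample_id, "SM": sample_id}],
        }
    )
    tid = {c: i for i, c in enumerate(reference.sequences)}
    records: list[pysam.AlignedSegment] = []

    def add_mapped(qname, flag, chrom, pos, cigar, mchrom, mpos, tlen, seq):
        a = pysam.AlignedSegment(header)
        a.query_name = qname
        a.flag = flag
        a.reference_id = tid[chrom]
        a.reference_start = pos
        a.mapping_quality = 60
        a.cigarstring = cigar
        a.next_reference_id = tid[mchrom]
        a.next_reference_start = mpos
        a.template_length = tlen
        a.query_sequence = seq
        records.append(a)

    def add_unmapped(qname, flag, chrom, pos, seq):
        a = pysam.AlignedSegment(header)
        a.query_name = qname
        a.flag = flag | 0x4
        a.reference_id = tid[chrom]
        a.reference_start = pos
        a.mapping_quality = 0
        a.next_reference_id = tid[chrom]
        a.next_reference_start = pos
        a.query_sequence = seq
        records.append(a)

    # --- background pairs: uniform along each chromosome -------------------
    for chrom, seq in reference.sequences.items():
        L = len(seq)
        n_pairs = int(round(config.target_coverage * L / (2 * rl)))
        tlens = np.clip(
            rng.normal(config.insert_mean, config.insert_sd, n_pairs),
            2 * rl, L,
        ).astype(int)
        starts = (rng.random(n_pairs) * (L - tlens)).astype(int)
        for i in range(n_pairs):
            s, t = int(starts[i]), int(tlens[i])
            p2 = s + t - rl
            qname = f"{sample_id}.bg.{chrom}.{i}"
            proper = 0x2 if t <= proper_cut else 0
            seq1 = _apply_errors(seq[s:s + rl], rng, config.error_rate)
            seq2 = _apply_errors(seq[p2:p2 + rl], rng, config.error_rate)
            add_mapped(qname, 0x1 | proper | 0x20 | 0x40, chrom, s, f"{rl}M",
                       chrom, p2, t, seq1)
            add_mapped(qname, 0x1 | proper | 0x10 | 0x80, chrom, p2, f"{rl}M",
                       chrom, s, -t, seq2)

    # --- retrocopy pairs: drawn from the retrocopy embedded in its insertion
    # flanks, so coverage over the retro is uniform at the per-copy dose and
    # junction fragments behave as they do in real data (flank mates map to
    # the insert site, junction-straddling mates are soft-clipped there).
    pad = int(config.insert_mean + 5 * config.insert_sd)
    for rc in config.carrier_table.get(sample_id, ()):
        gene = reference.genes[rc.parent_gene]
        tx = gene.transcripts[0]
        tx_len = tx.transcript_length
        tx_seq = "".join(
            reference.sequences[e.chrom][e.start:e.end] for e in tx.exons
        )
        retro_seq = tx_seq + "A" * config.polyA_length
        R = len(retro_seq)
        ins_seq = reference.sequences[rc.insert_chrom]
        lflank = _flank(ins_seq, rc.insert_pos - pad, rc.insert_pos)
        rflank = _flank(ins_seq, rc.insert_pos, rc.insert_pos + pad)
        ext_seq = lflank + retro_seq + rflank  # ext coord u ↔ index u + pad

        def place(lo: int, hi: int):
            """Map an ext-coordinate mate to (chrom, pos, end, cigar) or None
            (no reference home: poly-A only)."""
            retro_lo, retro_hi = max(lo, 0), min(hi, R)
            tx_hi = min(retro_hi, tx_len)
            tx_bases = max(0, tx_hi - retro_lo)
            flank_bases = max(0, -lo) + max(0, hi - R)
            if tx_bases == 0 and flank_bases == 0:
                return None
            if tx_bases >= flank_bases:
                blocks = _transcript_blocks(tx, retro_lo, tx_hi)
                cigar = _blocks_cigar(blocks, hi - tx_hi, retro_lo - lo)
                return gene.chrom, blocks[0][0], blocks[-1][1], cigar
            if -lo >= hi - R:  # left flank side
                a, b = lo, min(hi, 0)
                cigar = f"{b - a}M" + (f"{hi - b}S" if hi > b else "")
                return rc.insert_chrom, rc.insert_pos + a, rc.insert_pos + b, cigar
            a, b = max(lo, R), hi  # right flank side
            cigar = (f"{a - lo}S" if a > lo else "") + f"{b - a}M"
            return (rc.insert_chrom, rc.insert_pos + a - R,
                    rc.insert_pos + b - R, cigar)

        copy_cov = rc.copy_number * config.target_coverage / 2.0
        n_pairs = int(round(copy_cov * (R + config.insert_mean) / (2 * rl)))
        tlens = np.clip(
            rng.normal(config.insert_mean, config.insert_sd, n_pairs),
            2 * rl, pad,
        ).astype(int)
        starts = (rng.random(n_pairs) * (R + tlens)).astype(int) - tlens
        for i in range(n_pairs):
            s, t = int(starts[i]), int(tlens[i])
            qname = f"{sample_id}.rc.{rc.parent_gene}.{i}"
            mates, seqs = [], []
            for lo in (s, s + t - rl):
                mates.append(place(lo, lo + rl))
                seqs.append(
                    _apply_errors(ext_seq[lo + pad:lo + pad + rl], rng,
                                  config.error_rate)
                )
            (m1, m2), (seq1, seq2) = mates, seqs
            if m1 is None and m2 is None:
                continue
            if m1 is not None and m2 is not None:
                same = m1[0] == m2[0]
                outer = (max(m1[2], m2[2]) - min(m1[1], m2[1])) if same else 0
                proper = 0x2 if same and outer <= proper_cut else 0
                add_mapped(qname, 0x1 | proper | 0x20 | 0x40, m1[0], m1[1],
                           m1[3], m2[0], m2[1],
                           outer if same and m1[1] <= m2[1] else -outer if same else 0,
                           seq1)
                add_mapped(qname, 0x1 | proper | 0x10 | 0x80, m2[0], m2[1],
                           m2[3], m1[0], m1[1],
                           -outer if same and m1[1] <= m2[1] else outer if same else 0,
                           seq2)
            else:
                mapped, seq_m, um_seq, um_first = (
                    (m1, seq1, seq2, False) if m1 is not None
                    else (m2, seq2, seq1, True)
                )
                mapped_flag = 0x1 | 0x8 | (0x80 if um_first else 0x40)
                um_flag = 0x1 | (0x40 if um_first else 0x80)
                add_mapped(qname, mapped_flag, mapped[0], mapped[1],
                           mapped[3], mapped[0], mapped[1], 0, seq_m)
                add_unmapped(qname, um_flag, mapped[0], mapped[1], um_seq)

    records.sort(key=lambda a: (a.reference_id, a.reference_start, a.flag))
    bam_path = out_dir / f"{sample_id}.bam"
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bf:
        for rec in records:
            bf.write(rec)
    pysam.index(str(bam_path))
    return bam_path


def simulate_sv_vcf(
    config: SimConfig,
    reference: SimulatedReference,
    sample_id: str,
    out_path: str | Path,
) -> Path:
    """Emit the SV calls a short-read caller would report for this sample.

    Per planted retrocopy: one DEL per parent-gene intron (with
    ``exonic_miscall_prob``, one of them is extended into the adjacent exon,
    the occasional exonic miscall), plus breakend pairs linking positions
    within 100 bp of the parent gene's termini to the insertion site.
    Decoy DELs land in intergenic space.
    """
    rng = _sample_rng(config, sample_id, "vcf")
    out_path = Path(out_path)
    rows: list[tuple[str, int, str, str, str]] = []  # chrom, pos0, id, alt, info

    bnd_k = 0
    for rc in config.carrier_table.get(sample_id, ()):
        gene = reference.genes[rc.parent_gene]
        tx = gene.transcripts[0]
        from .genome_model import derive_introns

        introns = derive_introns(tx)
        exonic_idx = (
            int(rng.integers(0, len(introns)))
            if introns and rng.random() < config.exonic_miscall_prob
            else None
        )
        for i, intron in enumerate(introns):
            jit_s = int(rng.integers(5, 50))
            jit_e = int(rng.integers(5, 50))
            start = intron.start + jit_s
            end = intron.end - jit_e
            if i == exonic_idx:
                end = intron.end + min(50, config.exon_length)  # runs into exon
            rows.append(
                (gene.chrom, start, f"{sample_id}_del_{rc.parent_gene}_{i}",
                 "<DEL>", f"SVTYPE=DEL;END={end}")
            )
        # 5' and 3' junction breakends (1-based in ALT below)
        for terminus, ins_shift in (
            (gene.span.start, 0), (gene.span.end, config.tsd_length)
        ):
            delta = int(rng.integers(0, 101))
            pos_a = max(0, terminus - delta)
            pos_b = rc.insert_pos + ins_shift
            ida, idb = f"bnd_{sample_id}_{bnd_k}a", f"bnd_{sample_id}_{bnd_k}b"
            bnd_k += 1
            rows.append(
                (gene.chrom, pos_a, ida,
                 f"N[{rc.insert_chrom}:{pos_b + 1}[",
                 f"SVTYPE=BND;MATEID={idb}")
            )
            rows.append(
                (rc.insert_chrom, pos_b, idb,
                 f"N]{gene.chrom}:{pos_a + 1}]",
                 f"SVTYPE=BND;MATEID={ida}")
            )

    gene_spans = [g.span for g in reference.genes.values()]
    for d in range(config.n_decoy_dels):
        for _attempt in range(50):
            chrom = reference.chrom_names[
                int(rng.integers(0, len(reference.chrom_names)))
            ]
            length = int(rng.integers(500, 5001))
            start = int(rng.integers(0, len(reference.sequences[chrom]) - length))
            iv = GenomicInterval(chrom, start, start + length)
            if not any(iv.overlaps(sp) for sp in gene_spans):
                rows.append(
                    (chrom, start, f"{sample_id}_decoy_{d}", "<DEL>",
                     f"SVTYPE=DEL;END={start + length}")
                )
                break

    order = {c: i for i, c in enumerate(reference.chrom_names)}
    rows.sort(key=lambda r: (order[r[0]], r[1], r[2]))
    with open(out_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=retrofind-simulator seed={config.seed}\n")
        for chrom, seq in reference.sequences.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate id">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos0, rid, alt, info in rows:
            fh.write(f"{chrom}\t{pos0 + 1}\t{rid}\tN\t{alt}\t.\tPASS\t{info}\n")
    return out_path


def write_truth_manifest(
    config: SimConfig, reference: SimulatedReference, out_path: str | Path
) -> Path:
    """JSON ground truth: planted retrocopies, gene geometry, library stats."""
    manifest = {
        "seed": config.seed,
        "library": {
            "read_length": config.read_length,
            "insert_mean": config.insert_mean,
            "insert_sd": config.insert_sd,
            "target_coverage": config.target_coverage,
        },
        "genes": {
            gid: {
                "chrom": g.chrom,
                "start": g.span.start,
                "end": g.span.end,
                "n_exons": len(g.transcripts[0].exons),
                "transcript_length": g.transcripts[0].transcript_length,
            }
            for gid, g in reference.genes.items()
        },
        "samples": {
            s: [dataclasses.asdict(rc) for rc in config.carrier_table.get(s, [])]
            for s in config.samples
        },
    }
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out_path


@dataclass
class SimulatedCohort:
    reference: SimulatedReference
    bam_paths: dict[str, Path]
    vcf_paths: dict[str, Path]
    manifest_path: Path


def simulate_cohort(config: SimConfig, out_dir: str | Path) -> SimulatedCohort:
    """Reference + per-sample BAM and SV VCF + truth manifest."""
    out_dir = Path(out_dir)
    reference = generate_reference(config, out_dir)
    bams, vcfs = {}, {}
    for sample in config.samples:
        bams[sample] = simulate_individual(config, reference, sample, out_dir)
        vcfs[sample] = simulate_sv_vcf(
            config, reference, sample, out_dir / f"{sample}.sv.vcf"
        )
    manifest = write_truth_manifest(config, reference, out_dir / "truth.json")
    return SimulatedCohort(reference, bams, vcfs, manifest)


def make_cohort_config(
    n_samples: int,
    n_carriers: int,
    seed: int,
    copy_numbers: Optional[Sequence[int]] = None,
    **overrides,
) -> SimConfig:
    """Convenience cohort design: the first ``n_carriers`` samples each carry
    one retrocopy of a round-robin-chosen gene inserted at a random
    intergenic position (on the other chromosome where possible)."""
    base = SimConfig(seed=seed, **overrides)
    rng = np.random.default_rng([seed, zlib.crc32(b"cohort-design")])
    samples = tuple(f"S{i:03d}" for i in range(n_samples))
    gene_ids = [f"GENE{i + 1}" for i in range(base.n_genes)]
    chroms = [f"chr{i + 1}" for i in range(base.n_chromosomes)]
    # genes are placed round-robin over chromosomes from _GENE_MARGIN upward;
    # keep inserts in the tail region past every gene
    genes_per_chrom = -(-base.n_genes // base.n_chromosomes)
    occupied_end = _GENE_MARGIN + genes_per_chrom * (
        base.gene_span_length + _GENE_GAP
    )
    if occupied_end + 2000 >= base.chrom_length:
        raise ConfigError("no intergenic space left for insertion sites")
    carrier_table: dict[str, list[Retrocopy]] = {}
    for k in range(n_carriers):
        gi = k % len(gene_ids)
        gene = gene_ids[gi]
        gene_chrom = chroms[gi % base.n_chromosomes]
        ins_chrom = chroms[(chroms.index(gene_chrom) + 1) % len(chroms)]
        ins_pos = int(rng.integers(occupied_end + 1000, base.chrom_length - 1000))
        cn = copy_numbers[k % len(copy_numbers)] if copy_numbers else 1
        carrier_table[samples[k]] = [Retrocopy(gene, ins_chrom, ins_pos, cn)]
    return dataclasses.replace(
        base, samples=samples, carrier_table=carrier_table
    )
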