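# Methods

## The detection model

A non-reference retrocopy contributes reads that the aligner can only place
on the parent gene's exons. retrofind's detector formalises the resulting
signature as three conditions on a read pair, all evaluated against a gene
model:

* **(a) exon discordance** — both mates are assigned to exons of the same
  transcript, with different exon indices. A mate is assigned to the exon
  containing at least 50% of its aligned bases (gapped alignments are
  assessed on their aligned blocks). The half-in rule tolerates reads
  slightly overhanging exon edges while rejecting intronic reads; it is a
  package policy, since "mapped on different exons" alone does not fix a
  boundary behaviour.
* **(b) oversized template** — the pair's outer template length exceeds
  `max(1000 bp, μ + 3σ)`, with μ, σ estimated from the first 10,000 proper
  pairs of the same file (deterministic for a fixed file; template lengths
  outside a generous sanity window are discarded as artefacts; fewer than
  1,000 sampled pairs attaches a warning). μ+3σ is the conventional
  discordance cut; the 1 kb floor protects small-σ libraries and matches
  the intent that an informative pair spans an intron. The threshold is
  overridable (`--min-insert`).
* **(c) mapping quality** — both mates at MAPQ ≥ 10 (default), excluding
  multi-mapping noise in repetitive exons. Secondary, supplementary and
  duplicate records are ignored throughout.

A pair inside a gene with several isoforms is discordant if it is
discordant on at least one transcript (a retrocopy derives from one mRNA);
it is recorded once per gene, annotated with the transcript spanning the
most exons. Overlapping genes each evaluate the pair independently.

**Candidate calling.** Extracted mates are projected onto the transcript
they are discordant on: each assigned mate contributes one read and its
in-exon aligned bases. A transcript with *more than 20* reads (exclusive)
and mean projected coverage *of at least 3X* (inclusive; coverage = aligned
bases / spliced transcript length, i.e. depth, not breadth) is a processed
pseudogene candidate. The read threshold demands an exon chain rather than
a single deletion-like event; the coverage threshold mirrors the minimum
evidence SV callers require. When several transcripts of one gene pass,
the one with the highest read count is reported (ties break to the
lexicographically smallest transcript id), giving at most one candidate
row per parent gene and sample. Quantification is a deterministic
projection through the gene model rather than a re-alignment step: the
extracted reads are by construction exonic within one gene, so the
thresholds — not an aligner — define the method.

## Positioning

Breakpoint calls are read from VCF (deletions via `SVTYPE=DEL` + `END`,
breakends via the bracketed ALT; symbolic ALTs without a usable `END` are
skipped with a warning). A call becomes insert-site evidence for a parent
gene when one breakend lies within the terminus window (default 1,000 bp,
spanning typical library insert sizes) of the gene's start or end and the
partner breakend is on another chromosome or at least one gene-length away;
the partner's position is the evidence. Both end orderings are checked.

Evidence is clustered per chromosome by single linkage with a 500 bp gap:
positions exactly 500 apart collapse, 501 stay distinct, and chains merge
transitively (the collapse rule does not specify chaining; single linkage
is the choice made here and is pinned by tests against a transitive-closure
oracle). The representative position is the median, taking the lower of
the two middles for even counts — robust to a stray member at the fringe.

**Deletion miscalls.** Per sample and parent gene, the total count is all
DEL calls overlapping the gene span; the *high-priority* subset is those
overlapping at least one exon — the calls a consequence annotator would
flag as truncating. Exon overlap stands in for an external consequence
prediction, which keeps the count self-contained.

## Coverage validation

Per-base depth over the gene span counts aligned bases of primary,
non-duplicate reads (zeros included; no base-quality filtering — plain
depth counting). Depth is normalised per individual as
`norm = 2 · raw / mean(reference chromosome)`, placing the copy-neutral
diploid state at 2.0. The normalisation chromosome defaults to the largest
reference sequence (chr1 for human data, the conventional choice) and is
configurable, since toy genomes have no chr1.

The exon/intron ratio is the unweighted mean of per-exon means divided by
the unweighted mean of per-intron means — each feature counts equally
regardless of length, matching per-feature averaging of depth profiles. It
is undefined (reported as not applicable) for single-exon transcripts or
zero intron coverage. Expected values: 1.0 for non-carriers, 1.5 for one
extra intron-less copy (three exon copies per two intron copies), 2.0 for
two. On real data imperfect mapping pulls observed carrier ratios somewhat
below these ideals; the simulator does not model that loss, so synthetic
expectations sit at the theoretical values (see below).

## Enrichment and population statistics

The enrichment null draws, for each of 10,000 iterations, one chromosome
with probability proportional to its length and one uniform position on it,
from a single seeded generator (the seed is recorded in output headers).
The observed overlap count of insert sites with a feature class is compared
to the pooled null overlap fraction with an exact two-sided binomial test
("differs" is a two-sided question); a degenerate null fraction of 0 or 1
yields the degenerate binomial rather than an error. P-values are
Bonferroni-corrected across feature classes (`min(1, m·p)`).

Population summaries require a sample manifest including zero-candidate
individuals, otherwise carrier fractions are meaningless; a candidate from
a sample absent from the manifest is an error. The between-population
"diversity" comparison is ambiguous, so two labelled statistics are
reported: a carrier/non-carrier 2×2 chi-square (no continuity correction,
df = 1, with a warning when an expected cell is below 1) and, separately, a
unique-parent-genes vs other-candidates 2×2. Users pick the analogue that
matches their question.

## The simulator

The generator emulates a PCR-free short-read WGS experiment on a toy
genome. Defaults (chosen once as the study conditions): two 100 kb
chromosomes; five genes of four 300 bp exons separated by 1 kb introns
(4.2 kb genes, 1.2 kb transcripts); 120 bp paired-end reads with
Normal(400, 50) template lengths; 30X target coverage; base-error rate
0.001; 150 bp poly-A tail and 10 bp target-site duplication; per sample
0–2 planted retrocopies with copy number 1 or 2.

Background pairs are drawn uniformly per chromosome and mapped where they
originate. Retrocopy pairs are drawn from the retrocopy sequence (spliced
exons + poly-A) *embedded in its insertion-site flanks*, at per-copy
coverage `copy_number · target/2` — one copy is a heterozygous insertion
on a diploid background. Embedding in flanks makes coverage over the
retrocopy uniform at the per-copy dose (an isolated contig would have edge
ramps and interior over-density) and reproduces real junction behaviour:
mates falling in the flank map to the insertion locus, producing the
cross-chromosome pairs an SV caller converts into breakends, and mates
straddling a junction are soft-clipped on the minority side. A mate
spanning an exon–exon junction of the retrocopy is emitted as a spliced
(N-gap) alignment across the parent intron, so the pair's template length
is inflated by the skipped introns — the oversized-insert signature — and
exon depth is conserved exactly. Poly-A-only mates have no reference home
and are emitted as placed-unmapped records. Reads are placed, not
re-aligned: mapping ambiguity, mapping loss, SNP/indel background, repeat
elements and quality-score variation are deliberately not modelled. Tests
passing on this generator therefore demonstrate the correctness of the
detection arithmetic under ideal mapping, not robustness to real-data
mapping artefacts.

Each sample's SV VCF contains, per planted retrocopy, one deletion call
per parent-gene intron (the miscall signature; optionally one extended
into an adjacent exon to emulate the occasional exonic miscall), breakend
pairs linking positions within 100 bp of the gene's termini to the true
insert site (the 3′ junction offset by the TSD length), and configurable
intergenic decoy deletions. All outputs are deterministic functions of the
config seed and sample id; a JSON truth manifest records everything
planted.

## Numerical and degenerate-input choices

* Internal coordinates are 0-based half-open everywhere; GTF/VCF convert at
  the I/O boundary.
* Interval lookup is backed by an interval tree and required by tests to
  equal a naive all-pairs scan.
* `positioned_fraction` of an empty candidate set is "not applicable"
  (None), not 0.
* Clustering sorts before linkage, making it independent of input order.
* Library-stats estimation with zero proper pairs raises and points the
  user at the explicit threshold override.
* A single seeded generator per run; reruns with the same config are
  byte-identical.

## Problem sizes used in the checks

The bundled verification uses cohorts sized for a laptop: a 20-sample 30X
cohort with ten carriers for end-to-end recovery and a 16-sample 60X cohort
for copy-ratio calibration, on the default two-chromosome toy genome, plus
200-replicate Monte Carlo calibrations. At these sizes a heterozygous
carrier yields ~90–140 discordant mates per retrocopy against thresholds of
20 reads / 3X, so detection operates with a comfortable margin; the
exon/intron ratio means land within a few hundredths of the theoretical
1.0/1.5/2.0.

## Known limitations

* Pair-based evidence only: no split-read (supplementary alignment)
  support, no re-calling of SVs from alignments, no consequence annotation.
* No GC-bias or mappability correction in depth; no CNV segmentation.
* Duplicated (non-processed) pseudogenes, trans-spliced and fusion
  annotations, and CDS/UTR structure are out of scope.
* The ">20 reads" unit is individual mates (a pair contributes two), and
  "3X" is depth, not breadth; both are package interpretations pinned by
  tests.
* Expression-based quantification (TPM) is not performed; support comes
  from discordant mates alone.
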