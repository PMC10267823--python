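"""Monte Carlo feature-enrichment testing and cohort population summaries.

Insert sites are tested for enrichment in a feature class (segmental
duplications, reference processed pseudogenes, ...) against a length-aware
random null: for each of 10,000 iterations a chromosome is drawn with
probability proportional to its length and one uniform position is drawn on
it. The pooled null sites give the expected overlap fraction; an exact
two-sided binomial test compares the observed overlap fraction against it,
Bonferroni-corrected across feature classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome_model import FeatureTrack, GenomicInterval, intersect

DEFAULT_ITERATIONS = 10000


@dataclass(frozen=True)
class GenomeLayout:
    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths) or not self.chrom_names:
            raise ValueError("need equal, non-empty name/length lists")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be > 0")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths)

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeLayout":
        """Read a chrom-sizes (or .fai) file: name<TAB>length[<TAB>...]."""
        names, lengths = [], []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                fields = line.split("\t")
                names.append(fields[0])
                lengths.append(int(fields[1]))
        return cls(tuple(names), tuple(lengths))


@dataclass(frozen=True)
class EnrichmentResult:
    feature_name: str
    n_sites: int
    n_overlap: int
    observed_fraction: float
    null_fraction: float
    p_value: float
    p_adjusted: float


@dataclass(frozen=True)
class PopulationSummary:
    population: str
    n_individuals: int
    n_candidates: int
    unique_parent_genes: int
    carrier_fraction: float
    mean_candidates_per_individual: float


@dataclass(frozen=True)
class DiversityComparison:
    """Chi-square comparison of two populations.

    ``carrier_*`` compares carrier/non-carrier individual counts (2×2, no
    continuity correction, df=1). ``parent_gene_*`` is a separately labelled
    analogue comparing the share of candidates attributable to distinct
    parent genes. The two answer different questions; both are reported
    because "diversity" admits either reading.
    """

    population_a: str
    population_b: str
    carrier_chi2: float
    carrier_p: float
    parent_gene_chi2: Optional[float]
    parent_gene_p: Optional[float]
    df: int = 1
    warning: Optional[str] = None


def simulate_null_sites(
    layout: GenomeLayout, iterations: int = DEFAULT_ITERATIONS, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, int]]:
    """Random insert sites: chromosome ∝ length, position uniform on it."""
    if rng is None:
        rng = np.random.default_rng(seed)
    lengths = np.asarray(layout.chrom_lengths, dtype=float)
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(lengths), size=iterations, p=probs)
    positions = rng.integers(0, np.asarray(layout.chrom_lengths)[chrom_idx])
    return [
        (layout.chrom_names[i], int(p)) for i, p in zip(chrom_idx, positions)
    ]


def _overlap_count(sites: Sequence[tuple[str, int]], track: FeatureTrack) -> int:
    return sum(
        1 for chrom, pos in sites
        if intersect(GenomicInterval(chrom, pos, pos + 1), track)
    )


def enrichment_test(
    observed: Sequence[tuple[str, int]],
    track: FeatureTrack,
    null_sites: Sequence[tuple[str, int]],
    n_feature_classes: int = 1,
) -> EnrichmentResult:
    """Exact two-sided binomial test of observed vs Monte-Carlo overlap.

    The null overlap probability is estimated from ``null_sites``; a
    degenerate null fraction of 0 or 1 yields the degenerate binomial
    (p-value 1.0 when concordant, 0.0 when any site disagrees).
    """
    if not observed:
        raise ValueError("need at least one observed site")
    if not null_sites:
        raise ValueError("need at least one Monte Carlo site")
    n_sites = len(observed)
    n_overlap = _overlap_count(observed, track)
    null_fraction = _overlap_count(null_sites, track) / len(null_sites)
    p_value = float(
        sps.binomtest(n_overlap, n_sites, null_fraction, alternative="two-sided").pvalue
    )
    return EnrichmentResult(
        feature_name=track.name,
        n_sites=n_sites,
        n_overlap=n_overlap,
        observed_fraction=n_overlap / n_sites,
        null_fraction=null_fraction,
        p_value=p_value,
        p_adjusted=bonferroni(p_value, n_feature_classes),
    )


def bonferroni(p_value: float, n_tests: int) -> float:
    return min(1.0, p_value * n_tests)


def run_enrichment(
    observed: Sequence[tuple[str, int]],
    tracks: Sequence[FeatureTrack],
    layout: GenomeLayout,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int | None = None,
) -> list[EnrichmentResult]:
    """Test every feature class against one shared Monte Carlo null set."""
    null_sites = simulate_null_sites(layout, iterations, seed=seed)
    return [
        enrichment_test(observed, track, null_sites, n_feature_classes=len(tracks))
        for track in tracks
    ]


# ---------------------------------------------------------------------------
# Population summaries


def summarize_populations(
    cohort: pd.DataFrame, manifest: pd.DataFrame
) -> list[PopulationSummary]:
    """One summary per population.

    ``manifest`` must list every sequenced individual (sample_id,
    population), including those without candidates — the carrier fraction
    is meaningless otherwise. A candidate sample missing from the manifest
    is an error.
    """
    manifest = manifest.drop_duplicates("sample_id")
    known = set(manifest["sample_id"])
    stray = set(cohort["sample_id"]) - known if len(cohort) else set()
    if stray:
        raise ValueError(f"samples absent from manifest: {sorted(stray)}")
    out = []
    for pop, group in manifest.groupby("population", sort=True):
        samples = set(group["sample_id"])
        rows = cohort[cohort["sample_id"].isin(samples)] if len(cohort) else cohort
        carriers = rows["sample_id"].nunique() if len(rows) else 0
        out.append(
            PopulationSummary(
                population=str(pop),
                n_individuals=len(samples),
                n_candidates=len(rows),
                unique_parent_genes=rows["gene_id"].nunique() if len(rows) else 0,
                carrier_fraction=carriers / len(samples),
                mean_candidates_per_individual=len(rows) / len(samples),
            )
        )
    return out


def compare_diversity(
    summary_a: PopulationSummary,
    summary_b: PopulationSummary,
) -> DiversityComparison:
    """Chi-square tests of pseudogene diversity between two populations."""
    a_car = round(summary_a.carrier_fraction * summary_a.n_individuals)
    b_car = round(summary_b.carrier_fraction * summary_b.n_individuals)
    table = np.array(
        [
            [a_car, summary_a.n_individuals - a_car],
            [b_car, summary_b.n_individuals - b_car],
        ]
    )
    warning = None
    if table.min() == 0 and (table.sum(axis=0) == 0).any():
        raise ValueError("degenerate carrier table")
    chi2, p, _, expected = sps.chi2_contingency(table, correction=False)
    if expected.min() < 1:
        warning = "expected cell count < 1; chi-square approximation unreliable"

    pg_chi2 = pg_p = None
    if summary_a.n_candidates > 0 and summary_b.n_candidates > 0:
        pg_table = np.array(
            [
                [summary_a.unique_parent_genes,
                 summary_a.n_candidates - summary_a.unique_parent_genes],
                [summary_b.unique_parent_genes,
                 summary_b.n_candidates - summary_b.unique_parent_genes],
            ]
        )
        if pg_table.sum(axis=0).min() > 0 and pg_table.sum(axis=1).min() > 0:
            pg_chi2, pg_p, _, _ = sps.chi2_contingency(pg_table, correction=False)
    return DiversityComparison(
        population_a=summary_a.population,
        population_b=summary_b.population,
        carrier_chi2=float(chi2),
        carrier_p=float(p),
        parent_gene_chi2=None if pg_chi2 is None else float(pg_chi2),
        parent_gene_p=None if pg_p is None else float(pg_p),
        warning=warning,
    )


def write_enrichment_tsv(
    results: Iterable[EnrichmentResult], path: str | Path,
    header_lines: Iterable[str] = (),
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            "feature\tn_sites\tn_overlap\tobserved_fraction\t"
            "null_fraction\tp_value\tp_adjusted\n"
        )
        for r in results:
            fh.write(
                f"{r.feature_name}\t{r.n_sites}\t{r.n_overlap}\t"
                f"{r.observed_fraction:.6g}\t{r.null_fraction:.6g}\t"
                f"{r.p_value:.6g}\t{r.p_adjusted:.6g}\n"
            )


def write_population_tsv(
    summaries: Iterable[PopulationSummary], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "population\tn_individuals\tn_candidates\tunique_parent_genes\t"
            "carrier_fraction\tmean_candidates_per_individual\n"
        )
        for s in summaries:
            fh.write(
                f"{s.population}\t{s.n_individuals}\t{s.n_candidates}\t"
                f"{s.unique_parent_genes}\t{s.carrier_fraction:.6g}\t"
                f"{s.mean_candidates_per_individual:.6g}\n"
            )
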