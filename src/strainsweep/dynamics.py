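"""Genotype abundance, population capture and metagenomic-island dynamics.

Normalised genotype abundance follows the published formula: recruited
nucleotides as a percentage of total metagenome nucleotides, divided by the
genome size in Kbp; the genotype-level read filter is read coverage >= 0.7
with identity exactly 1.0 over the aligned span. The species-level filter
uses identity >= 0.95, the conventional viral species/population threshold.

Islands are intervals of low read recruitment relative to the genome's
median depth. The caller here is window-based (the published islands were
identified visually on recruitment plots): non-overlapping windows whose
mean depth falls at or below ``ratio_max`` times the genome median are
merged, and merged runs of at least ``min_island_len`` are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import RecruitmentHit
from .genomes import Genome
from .recruitment import DepthProfile

ISLAND = "island"
FILLED = "filled"
ABSENT = "absent_genome"


@dataclass
class AbundanceRecord:
    genome_id: str
    sample_id: str
    recruited_nt: int
    metagenome_nt: int
    normalized_abundance: float  # % of metagenome nt per Kbp of genome
    seq_depth: float  # mean per-position coverage


@dataclass
class PopulationCapture:
    genome_id: str
    sample_id: str
    n_reads_species: int
    n_reads_isolate: int
    capture_pct: float | None  # None when the species-level pool is empty


@dataclass
class Island:
    genome_id: str
    start: int
    end: int
    mean_depth: float
    genome_median_depth: float

    @property
    def ratio(self) -> float:
        if self.genome_median_depth == 0:
            return 0.0
        return self.mean_depth / self.genome_median_depth


def genotype_abundance(hits: list[RecruitmentHit], genome: Genome,
                       metagenome_nt: int, sample_id: str = "",
                       ) -> AbundanceRecord:
    """Normalised abundance from genotype-filtered hits.

    ``hits`` are expected to be pre-filtered to the genotype criterion
    (read_cov >= 0.7, identity == 1.0); zero passing hits give abundance 0.
    """
    if metagenome_nt <= 0:
        raise ValueError("metagenome_nt must be positive")
    recruited = int(sum(h.aligned_nt for h in hits))
    pct_of_metagenome = recruited / metagenome_nt * 100.0
    return AbundanceRecord(
        genome_id=genome.id,
        sample_id=sample_id,
        recruited_nt=recruited,
        metagenome_nt=metagenome_nt,
        normalized_abundance=pct_of_metagenome / (len(genome) / 1000.0),
        seq_depth=recruited / len(genome),
    )


def filter_genotype_hits(hits: list[RecruitmentHit], min_read_cov: float = 0.70,
                         identity: float = 1.0) -> list[RecruitmentHit]:
    """The quoted genotype-abundance filter: >=70% read coverage, exact
    identity over the aligned span."""
    return [h for h in hits if h.read_cov >= min_read_cov and h.identity >= identity]


def fold_change(abundance_now: float, abundance_prev: float) -> float | None:
    """Ratio of consecutive-timepoint abundances; None (below detection)
    when the previous abundance is 0."""
    if abundance_prev < 0 or abundance_now < 0:
        raise ValueError("abundances must be non-negative")
    if abundance_prev == 0:
        return None
    return abundance_now / abundance_prev


def population_capture(hits: list[RecruitmentHit], sample_id: str = "",
                       genome_id: str | None = None,
                       species_identity: float = 0.95,
                       isolate_identity: float = 1.0) -> PopulationCapture:
    """Fraction of the species-like population captured by the isolate.

    Denominator: reads at identity >= species threshold (0.95); numerator:
    reads identical to the isolate over their aligned span. ``hits`` must
    already carry the read-coverage filter.
    """
    gid = genome_id or (hits[0].genome_id if hits else "")
    n_species = sum(1 for h in hits if h.identity >= species_identity)
    n_isolate = sum(1 for h in hits if h.identity >= isolate_identity)
    pct = None if n_species == 0 else 100.0 * n_isolate / n_species
    return PopulationCapture(genome_id=gid, sample_id=sample_id,
                             n_reads_species=n_species,
                             n_reads_isolate=n_isolate, capture_pct=pct)


def detect_islands(profile: DepthProfile, window_bp: int = 500,
                   ratio_max: float = 0.2, min_island_len: int = 1000,
                   min_detect_depth: float = 5.0) -> list[Island]:
    """Call low-recruitment islands on one depth profile.

    Returns an empty list when the genome median depth does not exceed
    ``min_detect_depth`` (the genome is considered absent from the sample,
    so no island call is meaningful).
    """
    depth = profile.depth
    if window_bp > depth.size:
        raise ValueError("window_bp exceeds genome length")
    median = float(np.median(depth))
    if median <= min_detect_depth:
        return []
    n_windows = depth.size // window_bp
    edges = [(i * window_bp,
              (i + 1) * window_bp if i < n_windows - 1 else depth.size)
             for i in range(n_windows)]
    low = [float(np.mean(depth[a:b])) <= ratio_max * median for a, b in edges]

    islands: list[Island] = []
    i = 0
    while i < len(edges):
        if low[i]:
            j = i
            while j + 1 < len(edges) and low[j + 1]:
                j += 1
            start, end = edges[i][0], edges[j][1]
            if end - start >= min_island_len:
                islands.append(Island(
                    genome_id=profile.genome_id, start=start, end=end,
                    mean_depth=float(np.mean(depth[start:end])),
                    genome_median_depth=median,
                ))
            i = j + 1
        else:
            i += 1
    return islands


def island_timecourse(profiles: dict[str, DepthProfile], islands_t0: list[Island],
                      fill_ratio: float = 0.8, min_detect_depth: float = 5.0,
                      ) -> pd.DataFrame:
    """Re-evaluate t0 islands in every sample.

    Status per island and sample: ``absent_genome`` when the genome median
    depth is at or below the detection floor, ``filled`` when the island's
    depth ratio reaches ``fill_ratio`` (inclusive boundary), else ``island``.
    """
    rows = []
    for sample_id in sorted(profiles):
        profile = profiles[sample_id]
        for isl in islands_t0:
            if profile.genome_id != isl.genome_id:
                raise ValueError(
                    f"profile genome {profile.genome_id} != island genome "
                    f"{isl.genome_id}"
                )
            median = profile.median_depth()
            mean = float(np.mean(profile.depth[isl.start:isl.end]))
            if median <= min_detect_depth:
                status, ratio = ABSENT, np.nan
            else:
                ratio = mean / median
                status = FILLED if ratio >= fill_ratio else ISLAND
            rows.append({
                "island_id": f"{isl.genome_id}:{isl.start}-{isl.end}",
                "genome_id": isl.genome_id,
                "start": isl.start,
                "end": isl.end,
                "sample_id": sample_id,
                "ratio": ratio,
                "status": status,
            })
    return pd.DataFrame(rows)


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/|a|, overlap/|b|) for two half-open intervals."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if inter == 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))
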