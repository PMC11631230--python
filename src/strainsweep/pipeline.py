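"""End-to-end mesocosm replay: simulate -> recruit -> dynamics -> taxonomy
-> diversity -> distance.

The replay simulates an amended pond (logistic genotype sweep) and an
unamended control pond (flat trajectory) over the same community, maps every
sample against the isolate reference genomes, and derives the quantities the
study tracks: normalised genotype abundance with fold changes, the
species-level population-capture fraction, metagenomic-island status over
time, taxon counts, amplicon Shannon diversity and codon-variant statistics,
plus MinHash distances between whole read sets.

All stage outputs are plain TSV/BED/JSON and contain no timestamps, so a
rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .align import SeedIndex, align_reads
from .config import RunConfig
from .distance import Sketch, distance_matrix, minhash_sketch, write_sketches
from .diversity import (CodonVariantTable, PhylotypeTable, codon_variant_counts,
                        orf_pileup, phylotype_profile, rarefy, reference_kmer_set,
                        shannon_index)
from .dynamics import (FILLED, ISLAND, Island, detect_islands, filter_genotype_hits,
                       fold_change, genotype_abundance, island_timecourse,
                       population_capture, reciprocal_overlap)
from .genomes import Genome, write_fasta, write_orfs_bed
from .recruitment import DepthProfile, depth_profile, write_hits_tsv
from .simulate import (SampleReads, TruthRecord, simulate_amplicon_pool,
                       simulate_genus, simulate_timecourse)
from .taxonomy import (aai_matrix, assign_species_genus, assignments_to_frame,
                       cluster_intraspecies_groups, dereplicate_genomes,
                       predict_orfs, similarity_matrix)

DISPLAY_SCALE = 1000.0  # abundance values are small; reports multiply by 1000


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineResult:
    config: RunConfig
    genomes: list[Genome]
    truth: TruthRecord
    samples: dict[str, SampleReads]
    hits: dict[str, dict[str, list]]  # sample -> genome -> hits
    profiles: dict[str, dict[str, DepthProfile]]
    abundance: pd.DataFrame = field(default_factory=pd.DataFrame)
    capture: pd.DataFrame = field(default_factory=pd.DataFrame)
    islands_t0: list[Island] = field(default_factory=list)
    island_status: pd.DataFrame = field(default_factory=pd.DataFrame)
    taxonomy: pd.DataFrame = field(default_factory=pd.DataFrame)
    shannon: pd.DataFrame = field(default_factory=pd.DataFrame)
    phylotypes: pd.DataFrame = field(default_factory=pd.DataFrame)
    codon_variants: pd.DataFrame = field(default_factory=pd.DataFrame)
    sketches: dict[str, Sketch] = field(default_factory=dict)
    distances: pd.DataFrame = field(default_factory=pd.DataFrame)
    summary: dict = field(default_factory=dict)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(f"stage '{name}' failed: {exc}") from exc
        return inner
    return wrap


@_stage("simulate")
def _run_simulate(config: RunConfig):
    genomes, truth = simulate_genus(config.community)
    samples: dict[str, SampleReads] = {}
    for pond in config.ponds:
        for sample in simulate_timecourse(genomes, truth, config.community, pond):
            samples[sample.sample_id] = sample
    truth.validate()
    return genomes, truth, samples


@_stage("recruit")
def _run_recruit(config: RunConfig, references: list[Genome],
                 samples: dict[str, SampleReads]):
    index = SeedIndex(references, k=config.seed_k)
    hits: dict[str, dict[str, list]] = {}
    for sample_id in sorted(samples):
        sample = samples[sample_id]
        per_genome = align_reads(sample.ids, sample.seqs, index,
                                 min_read_cov=config.min_read_cov,
                                 query_step=config.query_step,
                                 best_per_genome=True)
        by_ref: dict[str, list] = {ref.id: [] for ref in references}
        for h in per_genome:
            by_ref[h.genome_id].append(h)
        hits[sample_id] = by_ref
    return hits


@_stage("dynamics")
def _run_dynamics(config: RunConfig, references: list[Genome],
                  samples: dict[str, SampleReads],
                  hits: dict[str, dict[str, list]], truth: TruthRecord):
    by_id = {g.id: g for g in references}
    metagenome_nt = {
        sid: sum(len(seq) for seq in sample.seqs)
        for sid, sample in samples.items()
    }

    abundance_rows = []
    capture_rows = []
    profiles: dict[str, dict[str, DepthProfile]] = {}
    for sample_id in sorted(samples):
        profiles[sample_id] = {}
        for ref_id in sorted(by_id):
            ref = by_id[ref_id]
            ref_hits = hits[sample_id][ref_id]
            genotype_hits = filter_genotype_hits(
                ref_hits, config.min_read_cov, config.isolate_identity)
            record = genotype_abundance(genotype_hits, ref,
                                        metagenome_nt[sample_id], sample_id)
            abundance_rows.append({
                "sample_id": sample_id,
                "genome_id": ref_id,
                "recruited_nt": record.recruited_nt,
                "metagenome_nt": record.metagenome_nt,
                "normalized_abundance": record.normalized_abundance,
                "display_abundance_x1000": record.normalized_abundance * DISPLAY_SCALE,
                "seq_depth": record.seq_depth,
            })
            cap = population_capture(ref_hits, sample_id, ref_id,
                                     config.species_identity,
                                     config.isolate_identity)
            capture_rows.append({
                "sample_id": sample_id,
                "genome_id": ref_id,
                "n_reads_species": cap.n_reads_species,
                "n_reads_isolate": cap.n_reads_isolate,
                "capture_pct": np.nan if cap.capture_pct is None else cap.capture_pct,
            })
            profiles[sample_id][ref_id] = depth_profile(
                ref_hits, ref, sample_id,
                identity_floor=config.island_identity_floor)

    abundance = pd.DataFrame(abundance_rows)
    abundance = abundance.sort_values(["genome_id", "sample_id"]).reset_index(drop=True)
    folds = []
    for gid, sub in abundance.groupby("genome_id"):
        prev = None
        for _, row in sub.iterrows():
            fc = None if prev is None else fold_change(
                row.normalized_abundance, prev)
            folds.append({
                "sample_id": row.sample_id, "genome_id": gid,
                "fold_change": np.nan if fc is None else fc,
                "below_detection_prev": prev == 0.0 if prev is not None else False,
            })
            prev = row.normalized_abundance
    abundance = abundance.merge(pd.DataFrame(folds), on=["sample_id", "genome_id"])

    # island calling on the sweep reference at the first amended timepoint,
    # then status of those islands in every sample of both ponds
    sweep_ref = truth.sweep_genotype
    t0 = min(config.community.timepoints_h)
    t0_sample = f"amended_t{t0:04d}"
    islands_t0: list[Island] = []
    island_status = pd.DataFrame()
    if t0_sample in profiles and sweep_ref in profiles[t0_sample]:
        islands_t0 = detect_islands(
            profiles[t0_sample][sweep_ref],
            window_bp=config.island_window_bp,
            ratio_max=config.island_ratio_max,
            min_island_len=config.min_island_len,
            min_detect_depth=config.min_detect_depth)
        if islands_t0:
            sweep_profiles = {sid: profiles[sid][sweep_ref] for sid in profiles}
            island_status = island_timecourse(
                sweep_profiles, islands_t0,
                fill_ratio=config.fill_ratio,
                min_detect_depth=config.min_detect_depth)
    return abundance, pd.DataFrame(capture_rows), profiles, islands_t0, island_status


@_stage("taxonomy")
def _run_taxonomy(config: RunConfig, genomes: list[Genome]):
    isolates = [g for g in genomes if g.labels.get("role") == "community"]
    nonredundant = dereplicate_genomes(isolates, min_len=config.derep_min_len)
    sim = similarity_matrix(nonredundant)
    assignments = assign_species_genus(sim, config.species_threshold,
                                       config.genus_threshold)
    by_species: dict[str, list[Genome]] = {}
    by_id = {g.id: g for g in nonredundant}
    for gid, a in assignments.items():
        by_species.setdefault(a.species_id, []).append(by_id[gid])
    for species_id in sorted(by_species):
        members = by_species[species_id]
        orfs = None if config.use_planted_orfs else {
            g.id: predict_orfs(g) for g in members}
        aai = aai_matrix(members, orfs)
        groups = cluster_intraspecies_groups(
            aai, members,
            n_groups=(config.n_groups_cut if len(members) > 1 else 1))
        for gid, ga in groups.items():
            assignments[gid].group_id = f"{species_id}_{ga.group_id}"
            assignments[gid].is_reference = ga.is_reference
    return assignments_to_frame(assignments), sim


def _amplicon_locus(genome: Genome, islands: list[tuple[int, int]]
                    ) -> tuple[int, int]:
    """Pick the planted ORF with the largest island overlap (tail-fiber
    analog); fall back to an in-frame mid-island window."""
    best, best_ov = None, 0
    for start, end, strand in genome.orfs:
        for istart, iend in islands:
            ov = max(0, min(end, iend) - max(start, istart))
            if ov > best_ov:
                best, best_ov = (start, end), ov
    if best is not None:
        start, end = best
        if end - start > 900:  # amplicon-sized piece of a long gene
            end = start + 900
        return start, end
    istart, iend = islands[0]
    mid = (istart + iend) // 2
    return mid - 300, mid + 300


@_stage("diversity")
def _run_diversity(config: RunConfig, genomes: list[Genome], truth: TruthRecord,
                   samples: dict[str, SampleReads],
                   hits: dict[str, dict[str, list]]):
    community = config.community
    by_id = {g.id: g for g in genomes}
    sweep = by_id[truth.sweep_genotype]
    islands = truth.island_intervals[sweep.id]
    locus = _amplicon_locus(sweep, [tuple(iv) for iv in islands])
    locus_seq = sweep.sequence[locus[0]:locus[1]]

    # phylotype pool: the isolate haplotype plus synthetic natural variants
    rng = np.random.default_rng([7, community.seed])
    phylotypes = {"isolate": locus_seq}
    from .genomes import decode, encode
    base = encode(locus_seq)
    for vi in range(config.n_phylotypes - 1):
        variant = base.copy()
        mask = rng.random(variant.size) < config.phylotype_divergence
        n = int(mask.sum())
        if n:
            variant[mask] = (variant[mask] + rng.integers(1, 4, size=n)) % 4
        phylotypes[f"variant_{vi + 1:02d}"] = decode(variant)

    f0, f_end = community.sweep_genotype_f0, community.sweep_f_end
    ref_kmers = reference_kmer_set(
        [g for g in genomes if g.labels.get("role") == "community"],
        config.phylotype_filter_k)

    shannon_rows = []
    phylotype_frames = []
    pools: dict[str, SampleReads] = {}
    for pond in config.ponds:
        traj = truth.sweep_trajectory.get(pond, {})
        for ti, t in enumerate(community.timepoints_h):
            f = traj.get(str(t), f0)
            progress = 0.0 if f_end == f0 else (f - f0) / (f_end - f0)
            p_iso = 0.02 + 0.88 * progress
            others = (1.0 - p_iso) / (len(phylotypes) - 1)
            freqs = {name: (p_iso if name == "isolate" else others)
                     for name in phylotypes}
            pond_idx = 0 if pond == "amended" else 1
            sub_seed = (community.seed * 1009 + pond_idx * 101 + ti) % (2 ** 31)
            sample_id = f"{pond}_t{t:04d}_amplicon"
            pool, used = simulate_amplicon_pool(
                phylotypes, freqs, config.amplicon_reads,
                config.amplicon_error_rate, sub_seed, sample_id, locus)
            truth.amplicon_truth[sample_id] = used
            pools[sample_id] = pool
            table = phylotype_profile(
                pool, None, config.min_match_frac, config.phylotype_filter_k,
                locus_id=f"{sweep.id}:{locus[0]}-{locus[1]}",
                sample_id=sample_id, reference_kmers=ref_kmers)
            rarefied = rarefy(table, config.rarefaction_depth, sub_seed)
            shannon_rows.append({
                "pond": pond, "time_h": t, "sample_id": sample_id,
                "n_phylotypes": len(rarefied.counts),
                "shannon": shannon_index(rarefied),
            })
            phylotype_frames.append(rarefied.to_frame())

    # codon variants: final amended sample mapped on the sweep reference
    te = max(community.timepoints_h)
    te_sample = f"amended_t{te:04d}"
    codon_frames = []
    pn_values = []
    if te_sample in hits and sweep.id in hits[te_sample]:
        reads_by_id = dict(zip(samples[te_sample].ids, samples[te_sample].seqs))
        ref_hits = hits[te_sample][sweep.id]
        for oi, orf in enumerate(sweep.orfs):
            segments = orf_pileup(ref_hits, reads_by_id, sweep, orf)
            orf_seq = sweep.sequence[orf[0]:orf[1]]
            table = codon_variant_counts(
                orf_seq, segments, config.min_aa_cov,
                config.min_mut_codon_count, config.min_mut_codon_freq,
                orf_id=f"{sweep.id}_orf{oi + 1:03d}")
            frame = table.to_frame()
            if not frame.empty:
                codon_frames.append(frame)
            if table.pn_fraction is not None:
                pn_values.append(table.pn_fraction)

    shannon = pd.DataFrame(shannon_rows)
    phylotype_table = (pd.concat(phylotype_frames, ignore_index=True)
                       if phylotype_frames else pd.DataFrame())
    codon_table = (pd.concat(codon_frames, ignore_index=True)
                   if codon_frames else pd.DataFrame())
    return shannon, phylotype_table, codon_table, pn_values, pools


@_stage("distance")
def _run_distance(config: RunConfig, samples: dict[str, SampleReads]):
    sketches = {
        sid: minhash_sketch(samples[sid], k=config.sketch_k,
                            s=config.sketch_size,
                            min_count=config.sketch_min_count)
        for sid in sorted(samples)
    }
    return sketches, distance_matrix(sketches)


def run_pipeline(config: RunConfig, out_dir: str | os.PathLike | None = None
                 ) -> PipelineResult:
    """Execute the full replay; write the report bundle when out_dir (or
    config.out_dir) is set."""
    config.validate()
    out = Path(out_dir or config.out_dir) if (out_dir or config.out_dir) else None

    genomes, truth, samples = _run_simulate(config)
    by_id = {g.id: g for g in genomes}
    sweep_species = truth.genomes[truth.sweep_genotype]["species"]
    other_species = sorted({
        info["species"] for info in truth.genomes.values()
        if info.get("role") == "community" and info["species"] != sweep_species
    })
    references = [by_id[truth.sweep_genotype]] + [
        next(by_id[g] for g in sorted(truth.genomes)
             if truth.genomes[g].get("role") == "community"
             and truth.genomes[g]["species"] == sp)
        for sp in other_species
    ]

    hits = _run_recruit(config, references, samples)
    abundance, capture, profiles, islands_t0, island_status = _run_dynamics(
        config, references, samples, hits, truth)

    result = PipelineResult(config=config, genomes=genomes, truth=truth,
                            samples=samples, hits=hits, profiles=profiles,
                            abundance=abundance, capture=capture,
                            islands_t0=islands_t0, island_status=island_status)

    if config.run_taxonomy:
        result.taxonomy, _sim = _run_taxonomy(config, genomes)
    pools: dict[str, SampleReads] = {}
    pn_values: list[float] = []
    if config.run_diversity:
        (result.shannon, result.phylotypes, result.codon_variants,
         pn_values, pools) = _run_diversity(config, genomes, truth, samples, hits)
    if config.run_distance:
        result.sketches, result.distances = _run_distance(config, samples)

    result.summary = _summarize(config, result, pn_values)
    if out is not None:
        _write_bundle(out, config, result, pools)
    return result


def _summarize(config: RunConfig, result: PipelineResult,
               pn_values: list[float]) -> dict:
    community = config.community
    truth = result.truth
    sweep_id = truth.sweep_genotype
    t0 = min(community.timepoints_h)
    te = max(community.timepoints_h)

    summary: dict = {
        "package_version": __version__,
        "seed": community.seed,
        "genome_length_bp": len(result.genomes[0]),
        "sweep_genotype": sweep_id,
        "timepoints_h": list(community.timepoints_h),
    }

    # per-pond abundance trajectory of the sweep reference (display scale)
    ab = result.abundance
    trajectories: dict[str, list[float]] = {}
    for pond in config.ponds:
        values = []
        for t in community.timepoints_h:
            sid = f"{pond}_t{t:04d}"
            row = ab[(ab.sample_id == sid) & (ab.genome_id == sweep_id)]
            values.append(float(row.display_abundance_x1000.iloc[0])
                          if len(row) else np.nan)
        trajectories[pond] = values
    summary["sweep_abundance_x1000"] = trajectories
    summary["sweep_truth_trajectory"] = truth.sweep_trajectory

    t0_amended = f"amended_t{t0:04d}"
    if t0_amended in truth.reads:
        summary["sweep_reads_t0"] = sum(
            1 for origin in truth.reads[t0_amended].values()
            if origin[0] == sweep_id)

    cap = result.capture
    te_amended = f"amended_t{te:04d}"
    cap_row = cap[(cap.sample_id == te_amended) & (cap.genome_id == sweep_id)]
    if len(cap_row):
        value = cap_row.capture_pct.iloc[0]
        summary["capture_pct_final"] = None if pd.isna(value) else float(value)

    # islands: calls at t0 plus truth overlap and the island->filled signal
    truth_islands = [tuple(iv) for iv in truth.island_intervals[sweep_id]]
    island_info = []
    for isl in result.islands_t0:
        overlap = max((reciprocal_overlap((isl.start, isl.end), ti)
                       for ti in truth_islands), default=0.0)
        island_info.append({"start": isl.start, "end": isl.end,
                            "ratio": isl.ratio,
                            "truth_reciprocal_overlap": overlap})
    summary["islands_t0"] = island_info
    status = result.island_status
    transitions = {}
    for pond in config.ponds:
        s0 = status[status.sample_id == f"{pond}_t{t0:04d}"]
        s1 = status[status.sample_id == f"{pond}_t{te:04d}"]
        if len(s0) and len(s1):
            transitions[pond] = {
                "t0_status": sorted(set(s0.status)),
                "tend_status": sorted(set(s1.status)),
                "island_to_filled": bool((s0.status == ISLAND).all()
                                         and (s1.status == FILLED).all()),
            }
    summary["island_transition"] = transitions

    if len(result.taxonomy):
        tax = result.taxonomy
        summary["taxonomy"] = {
            "n_nonredundant": int(len(tax)),
            "n_genera": int(tax.genus.nunique()),
            "n_species": int(tax.species.nunique()),
            "n_groups_largest_species": int(
                tax[tax.species == tax.species.mode()[0]].group.nunique()),
        }

    if len(result.shannon):
        sh = result.shannon
        summary["shannon"] = {
            pond: {
                str(int(row.time_h)): float(row.shannon)
                for _, row in sh[sh.pond == pond].iterrows()
            } for pond in config.ponds
        }

    if pn_values:
        summary["pn_fraction"] = {
            "n_orfs_with_variants": len(pn_values),
            "mean": float(np.mean(pn_values)),
        }

    if len(result.distances):
        d = result.distances
        dist = {}
        for pond in config.ponds:
            a, b = f"{pond}_t{t0:04d}", f"{pond}_t{te:04d}"
            if a in d.index and b in d.index:
                dist[f"{pond}_t0_vs_tend"] = float(d.loc[a, b])
        summary["mash_distance"] = dist
    return summary


def _write_bundle(out: Path, config: RunConfig, result: PipelineResult,
                  pools: dict[str, SampleReads]) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(result.genomes, out / "genomes.fasta")
    write_orfs_bed(result.genomes, out / "orfs.bed")
    result.truth.to_json(out / "truth.json")

    reads_dir = out / "reads"
    reads_dir.mkdir(exist_ok=True)
    for sid in sorted(result.samples):
        result.samples[sid].to_fastq(reads_dir / f"{sid}.fastq")
    for sid in sorted(pools):
        pools[sid].to_fastq(reads_dir / f"{sid}.fastq")

    hits_dir = out / "hits"
    hits_dir.mkdir(exist_ok=True)
    for sid in sorted(result.hits):
        for gid in sorted(result.hits[sid]):
            write_hits_tsv(result.hits[sid][gid],
                           hits_dir / f"{sid}__{gid}.tsv")

    depth_dir = out / "depth"
    depth_dir.mkdir(exist_ok=True)
    for sid in sorted(result.profiles):
        for gid, profile in sorted(result.profiles[sid].items()):
            profile.to_tsv(depth_dir / f"{sid}__{gid}.tsv")

    result.abundance.to_csv(out / "abundance.tsv", sep="\t", index=False,
                            float_format="%.8g")
    result.capture.to_csv(out / "capture.tsv", sep="\t", index=False,
                          float_format="%.8g")
    with open(out / "islands.bed", "w") as fh:
        for isl in result.islands_t0:
            fh.write(f"{isl.genome_id}\t{isl.start}\t{isl.end}\t"
                     f"island\t{isl.ratio:.4f}\t+\n")
    if len(result.island_status):
        result.island_status.to_csv(out / "island_status.tsv", sep="\t",
                                    index=False, float_format="%.6g")
    if len(result.taxonomy):
        result.taxonomy.to_csv(out / "taxonomy.tsv", sep="\t", index=False)
    if len(result.shannon):
        result.shannon.to_csv(out / "shannon.tsv", sep="\t", index=False,
                              float_format="%.8g")
    if len(result.phylotypes):
        result.phylotypes.to_csv(out / "phylotypes.tsv", sep="\t", index=False)
    if len(result.codon_variants):
        result.codon_variants.to_csv(out / "codon_variants.tsv", sep="\t",
                                     index=False)
    if result.sketches:
        write_sketches(result.sketches, out / "sketches.json")
    if len(result.distances):
        result.distances.to_csv(out / "distances.tsv", sep="\t",
                                float_format="%.8g")

    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, sort_keys=True, indent=1)
    with open(out / "run_log.json", "w") as fh:
        json.dump({"package_version": __version__,
                   "resolved_config": config.to_dict()}, fh,
                  sort_keys=True, indent=1)
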