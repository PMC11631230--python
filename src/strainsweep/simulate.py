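"""Synthetic viral community generator.

Emulates the mesocosm system the analysis was designed for: a genus backbone
gives rise to two species (diverged everywhere, and strongly diverged inside
a species-specific hypervariable island), one species carries nine
intra-species variant groups, and a single rare genotype of that species
sweeps along a logistic trajectory over the sampled time course while reads
from unrelated background genomes dilute every sample.

Mutations are substitutions only, applied as i.i.d. per-site resampling among
the three other bases (back-substitutions therefore occur and planted
divergences are validated post hoc by direct site counting). ORFs are planted
as non-overlapping forward-strand start-to-stop frames covering roughly half
of each genome, at identical coordinates in every derived genome.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .config import CommunityConfig, ConfigError
from .genomes import Genome, decode, encode, revcomp_codes

# fixed per-operation offsets for the RNG stream (single stream per operation)
_OP_GENUS = 1
_OP_TIMECOURSE = 2
_OP_AMPLICON = 3

_STOP_CODONS = ((3, 0, 0), (3, 0, 2), (3, 2, 0))  # TAA, TAG, TGA
_START_CODON = (0, 3, 2)  # ATG


class CommunityStructureError(ConfigError):
    """Planted divergences violate the species/genus identity bands."""


@dataclass
class SampleReads:
    """A single sequencing sample: parallel id/sequence lists."""

    sample_id: str
    ids: list[str]
    seqs: list[str]

    def __len__(self) -> int:
        return len(self.ids)

    def to_fastq(self, path: str | os.PathLike, quality_char: str = "I") -> None:
        with open(path, "w") as fh:
            for rid, seq in zip(self.ids, self.seqs):
                fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")

    @classmethod
    def from_fastq(cls, path: str | os.PathLike, sample_id: str | None = None) -> "SampleReads":
        ids, seqs = [], []
        with open(path) as fh:
            while True:
                header = fh.readline()
                if not header:
                    break
                seq = fh.readline().strip()
                fh.readline()
                fh.readline()
                ids.append(header[1:].split()[0])
                seqs.append(seq.upper())
        name = sample_id or os.path.splitext(os.path.basename(str(path)))[0]
        return cls(name, ids, seqs)


@dataclass
class TruthRecord:
    """Machine-readable ground truth for parameter-recovery tests."""

    genomes: dict[str, dict] = field(default_factory=dict)
    island_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    sweep_genotype: str | None = None
    sweep_trajectory: dict = field(default_factory=dict)
    abundances: dict[str, dict[str, float]] = field(default_factory=dict)
    reads: dict[str, dict[str, tuple[str, int, int, str]]] = field(default_factory=dict)
    amplicon_truth: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        for sample, ab in self.abundances.items():
            total = sum(ab.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"sample {sample}: abundances sum to {total}")
        seen: set[str] = set()
        for sample_reads in self.reads.values():
            for rid in sample_reads:
                if rid in seen:
                    raise ValueError(f"duplicate read id {rid}")
                seen.add(rid)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "genomes": self.genomes,
            "island_intervals": {
                g: [list(iv) for iv in ivs] for g, ivs in self.island_intervals.items()
            },
            "sweep_genotype": self.sweep_genotype,
            "sweep_trajectory": self.sweep_trajectory,
            "abundances": self.abundances,
            "reads": {
                s: {r: list(v) for r, v in d.items()} for s, d in self.reads.items()
            },
            "amplicon_truth": self.amplicon_truth,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "TruthRecord":
        with open(path) as fh:
            payload = json.load(fh)
        truth = cls(
            genomes=payload["genomes"],
            island_intervals={
                g: [tuple(iv) for iv in ivs]
                for g, ivs in payload["island_intervals"].items()
            },
            sweep_genotype=payload["sweep_genotype"],
            sweep_trajectory=payload["sweep_trajectory"],
            abundances=payload["abundances"],
            reads={
                s: {r: tuple(v) for r, v in d.items()}
                for s, d in payload["reads"].items()
            },
            amplicon_truth=payload.get("amplicon_truth", {}),
        )
        return truth


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator,
            mask: np.ndarray | None = None,
            profile: np.ndarray | None = None) -> np.ndarray:
    """Resample sites at the given per-site rate among the 3 other bases.

    Replacement bases are drawn from ``profile`` (the genome's base
    composition) renormalised without the current base, so divergence does
    not erode the planted GC content; None falls back to uniform.
    """
    out = codes.copy()
    hit = rng.random(codes.size) < rate
    if mask is not None:
        hit &= mask
    n = int(hit.sum())
    if not n:
        return out
    if profile is None:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n)) % 4
        return out
    hit_idx = np.nonzero(hit)[0]
    for base in range(4):
        sel = hit_idx[out[hit_idx] == base]
        if sel.size == 0:
            continue
        others = np.array([b for b in range(4) if b != base], dtype=np.uint8)
        p = profile[others] / profile[others].sum()
        out[sel] = rng.choice(others, size=sel.size, p=p)
    return out


def _base_profile(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_backbone(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _plant_orfs(codes: np.ndarray, gc: float, rng: np.random.Generator
                ) -> list[tuple[int, int, str]]:
    """Overwrite ~50% of the backbone with stop-free forward-frame ORFs.

    Each ORF is ATG ... (non-stop codons) ... stop; intervals are
    non-overlapping and identical across all genomes derived later.
    """
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    length = codes.size
    orfs: list[tuple[int, int, str]] = []
    pos = int(rng.integers(150, 400))
    stop_set = set(_STOP_CODONS)
    while pos + 310 < length - 150:
        n_codons = int(rng.integers(100, 501))  # 300..1503 nt
        orf_len = 3 * n_codons
        end = pos + orf_len
        if end > length - 150:
            end = length - 150 - ((length - 150 - pos) % 3)
            orf_len = end - pos
            if orf_len < 300:
                break
            n_codons = orf_len // 3
        body = rng.choice(4, size=(n_codons + 8, 3), p=p).astype(np.uint8)
        kept = [c for c in map(tuple, body) if c not in stop_set][: n_codons - 2]
        while len(kept) < n_codons - 2:  # top up in the unlikely shortfall
            extra = tuple(rng.choice(4, size=3, p=p))
            if extra not in stop_set:
                kept.append(extra)
        stop = _STOP_CODONS[int(rng.integers(0, 3))]
        orf_codes = np.array(
            [_START_CODON] + kept + [stop], dtype=np.uint8
        ).reshape(-1)
        codes[pos:end] = orf_codes
        orfs.append((pos, end, "+"))
        pos = end + int(rng.integers(300, 1500))
    return orfs


def pairwise_site_identity(a: str | np.ndarray, b: str | np.ndarray) -> float:
    """Direct site-by-site identity of two equal-length sequences."""
    ca = encode(a) if isinstance(a, str) else a
    cb = encode(b) if isinstance(b, str) else b
    if ca.size != cb.size:
        raise ValueError("sequences differ in length")
    return float(np.mean(ca == cb))


def simulate_genus(config: CommunityConfig) -> tuple[list[Genome], TruthRecord]:
    """Generate the viral genus plus background genomes and the truth record.

    Species 1 carries ``n_groups`` variant groups of ``genomes_per_group``
    genomes each; every further species is represented by a single genome
    (as in the study system, where one species had one isolate). The first
    genome of group 1 is flagged as the sweep genotype.
    """
    config.validate()
    rng = np.random.default_rng([_OP_GENUS, config.seed])
    length = config.genome_length_bp or int(rng.integers(44000, 46001))
    islands = config.resolved_island_intervals(length)
    island_mask = np.zeros(length, dtype=bool)
    for start, end in islands:
        island_mask[start:end] = True

    backbone = _random_backbone(length, config.gc_fraction, rng)
    orfs = _plant_orfs(backbone, config.gc_fraction, rng)
    profile = _base_profile(config.gc_fraction)

    genomes: list[Genome] = []
    truth = TruthRecord()
    for si in range(config.n_species):
        anc = _mutate(backbone, config.interspecies_divergence, rng,
                      ~island_mask, profile)
        anc = _mutate(anc, config.island_divergence, rng, island_mask, profile)
        n_groups = config.n_groups if si == 0 else 1
        per_group = config.genomes_per_group if si == 0 else 1
        for gi in range(n_groups):
            group_anc = _mutate(anc, config.intergroup_divergence, rng,
                                profile=profile)
            for mi in range(per_group):
                member = _mutate(group_anc, config.intragroup_divergence, rng,
                                 profile=profile)
                gid = f"sp{si + 1}_g{gi + 1:02d}_m{mi + 1}"
                species = f"species_{si + 1}"
                group = f"{species}_group_{gi + 1:02d}"
                genome = Genome(
                    id=gid,
                    sequence=decode(member),
                    orfs=list(orfs),
                    labels={"species": species, "group": group, "role": "community"},
                )
                genomes.append(genome)
                truth.genomes[gid] = {
                    "species": species,
                    "group": group,
                    "role": "community",
                }
                truth.island_intervals[gid] = [tuple(iv) for iv in islands]

    truth.sweep_genotype = "sp1_g01_m1"
    truth.genomes[truth.sweep_genotype]["is_sweep"] = True

    for bi in range(config.n_background_genomes):
        seq = _random_backbone(length, 0.5, rng)
        gid = f"background_{bi + 1}"
        genomes.append(
            Genome(id=gid, sequence=decode(seq), labels={"species": "background",
                                                         "role": "background"})
        )
        truth.genomes[gid] = {"species": "background", "role": "background"}

    _check_planted_structure(genomes, config)
    return genomes, truth


def _check_planted_structure(genomes: list[Genome], config: CommunityConfig) -> None:
    by_species: dict[str, list[Genome]] = {}
    for g in genomes:
        if g.labels.get("role") == "community":
            by_species.setdefault(g.labels["species"], []).append(g)
    species_names = sorted(by_species)
    for name in species_names:
        members = by_species[name]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                ident = pairwise_site_identity(members[i].codes, members[j].codes)
                if ident <= config.species_identity_threshold:
                    raise CommunityStructureError(
                        f"within-species identity {ident:.4f} "
                        f"({members[i].id} vs {members[j].id}) <= "
                        f"{config.species_identity_threshold}"
                    )
    for i in range(len(species_names)):
        for j in range(i + 1, len(species_names)):
            a = by_species[species_names[i]][0]
            b = by_species[species_names[j]][0]
            ident = pairwise_site_identity(a.codes, b.codes)
            if not (config.genus_identity_threshold < ident
                    < config.species_identity_threshold):
                raise CommunityStructureError(
                    f"between-species identity {ident:.4f} ({a.id} vs {b.id}) "
                    f"outside ({config.genus_identity_threshold}, "
                    f"{config.species_identity_threshold})"
                )


def sweep_trajectory(timepoints: list[int], f0: float, f_end: float) -> list[float]:
    """Logistic sweep with midpoint pinned at the median timepoint.

    f(t) = A / (1 + exp(-r (t - m))); A and r solve f(t0)=f0, f(tend)=f_end.
    A flat trajectory (f_end == f0) models the unamended control pond.
    """
    tp = np.asarray(timepoints, dtype=float)
    if tp.size == 0:
        return []
    if f_end == f0 or tp.size == 1:
        return [f0] * tp.size
    if f_end < f0:
        raise ValueError("sweep requires f_end >= f0")
    m = float(np.median(tp))
    t0, te = tp[0], tp[-1]

    def gap(r: float) -> float:
        amp = f_end / expit(r * (te - m))
        return amp * expit(r * (t0 - m)) - f0

    r = brentq(gap, 1e-9, 10.0, xtol=1e-12)
    amp = f_end / expit(r * (te - m))
    return [float(amp * expit(r * (t - m))) for t in tp]


def community_abundances(truth: TruthRecord, f_sweep: float,
                         background_fraction: float) -> dict[str, float]:
    """Relative abundances at one timepoint.

    The sweep genotype holds f_sweep; its within-species companions (the rest
    of the natural species-like population that rises with it) share another
    f_sweep; resident relatives (the other species) absorb the remainder and
    decline as the sweep proceeds; background genomes hold a fixed share.
    Weights are normalised to sum to one.
    """
    sweep = truth.sweep_genotype
    sweep_species = truth.genomes[sweep]["species"]
    companions = [g for g, info in truth.genomes.items()
                  if info.get("role") == "community"
                  and info["species"] == sweep_species and g != sweep]
    residents = [g for g, info in truth.genomes.items()
                 if info.get("role") == "community"
                 and info["species"] != sweep_species]
    background = [g for g, info in truth.genomes.items()
                  if info.get("role") == "background"]

    weights: dict[str, float] = {g: 0.0 for g in truth.genomes}
    weights[sweep] = f_sweep
    for g in companions:
        weights[g] = f_sweep / max(1, len(companions))
    resident_mass = max(0.0, 1.0 - background_fraction - 2.0 * f_sweep)
    for g in residents:
        weights[g] = resident_mass / max(1, len(residents))
    for g in background:
        weights[g] = background_fraction / max(1, len(background))
    total = sum(weights.values())
    return {g: w / total for g, w in weights.items()}


def simulate_timecourse(genomes: list[Genome], truth: TruthRecord,
                        config: CommunityConfig, pond: str = "amended",
                        ) -> list[SampleReads]:
    """Draw one read sample per timepoint from the planted abundances.

    Reads have fixed length, uniform start positions, random strand and
    per-base substitution errors; ids encode nothing about origin (origin
    lives only in the truth record). The control pond uses a flat sweep
    trajectory (f stays at f0).
    """
    if config.reads_per_sample <= 0:
        raise ValueError("reads_per_sample must be positive")
    rng = np.random.default_rng(
        [_OP_TIMECOURSE, 0 if pond == "amended" else 1, config.seed]
    )
    f_end = config.sweep_f_end if pond == "amended" else config.sweep_genotype_f0
    traj = sweep_trajectory(list(config.timepoints_h), config.sweep_genotype_f0, f_end)
    truth.sweep_trajectory[pond] = {
        str(t): f for t, f in zip(config.timepoints_h, traj)
    }

    by_id = {g.id: g for g in genomes}
    order = sorted(truth.genomes)
    samples: list[SampleReads] = []
    rl = config.read_length_bp
    for t, f in zip(config.timepoints_h, traj):
        sample_id = f"{pond}_t{t:04d}"
        ab = community_abundances(truth, f, config.background_fraction)
        truth.abundances[sample_id] = {g: ab[g] for g in order}
        counts = rng.multinomial(config.reads_per_sample, [ab[g] for g in order])

        all_seqs: list[str] = []
        origins: list[tuple[str, int, int, str]] = []
        for gid, n in zip(order, counts):
            if n == 0:
                continue
            genome = by_id[gid]
            codes = genome.codes
            starts = rng.integers(0, len(genome) - rl + 1, size=n)
            windows = np.lib.stride_tricks.sliding_window_view(codes, rl)[starts].copy()
            flip = rng.random(n) < 0.5
            for row in np.nonzero(flip)[0]:
                windows[row] = revcomp_codes(windows[row])
            err = rng.random(windows.shape) < config.error_rate
            n_err = int(err.sum())
            if n_err:
                windows[err] = (windows[err] + rng.integers(1, 4, size=n_err)) % 4
            for row in range(n):
                all_seqs.append(decode(windows[row]))
                strand = "-" if flip[row] else "+"
                origins.append((gid, int(starts[row]), int(starts[row]) + rl, strand))

        perm = rng.permutation(len(all_seqs))
        ids = [f"{sample_id}:{i:06d}" for i in range(len(all_seqs))]
        sample = SampleReads(sample_id, ids, [all_seqs[p] for p in perm])
        truth.reads[sample_id] = {
            ids[i]: origins[perm[i]] for i in range(len(ids))
        }
        samples.append(sample)
    return samples


def simulate_amplicon_pool(phylotypes: dict[str, str], freqs: dict[str, float],
                           n_reads: int, error_rate: float, seed: int,
                           sample_id: str = "amplicon",
                           locus_interval: tuple[int, int] | None = None,
                           ) -> tuple[SampleReads, dict[str, float]]:
    """Sample amplicon-length reads from named phylotype sequences.

    Returns the pool and the truth frequency distribution actually used.
    """
    if not freqs:
        raise ValueError("empty phylotype frequency vector")
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"phylotype frequencies sum to {total}, expected 1")
    missing = set(freqs) - set(phylotypes)
    if missing:
        raise ValueError(f"frequencies name unknown phylotypes: {sorted(missing)}")
    rng = np.random.default_rng([_OP_AMPLICON, seed])
    names = sorted(freqs)
    counts = rng.multinomial(n_reads, [freqs[n] for n in names])
    seqs: list[str] = []
    for name, n in zip(names, counts):
        codes = encode(phylotypes[name])
        for _ in range(n):
            read = codes.copy()
            err = rng.random(read.size) < error_rate
            n_err = int(err.sum())
            if n_err:
                read[err] = (read[err] + rng.integers(1, 4, size=n_err)) % 4
            seqs.append(decode(read))
    perm = rng.permutation(len(seqs))
    ids = [f"{sample_id}:{i:06d}" for i in range(len(seqs))]
    pool = SampleReads(sample_id, ids, [seqs[p] for p in perm])
    return pool, {n: freqs[n] for n in names}
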