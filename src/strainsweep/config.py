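"""Configuration objects for the synthetic community and the full replay run.

The community defaults encode the study system being emulated: a viral genus
of two species (44-46 kb genomes, GC 0.63), one species carrying nine
intra-species variant groups, a ~3 kb species-specific hypervariable island,
and a rare genotype sweeping from 1e-4 to 0.5 relative abundance over a
0-672 h time course.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates its documented invariants."""


def _expected_pair_identity(d1: float, d2: float) -> float:
    # Two branches mutated independently from a common ancestor; a mutated
    # site is resampled uniformly among the three other bases, so two
    # independently mutated sites coincide with probability 1/3.
    return (1 - d1) * (1 - d2) + d1 * d2 / 3.0


@dataclass
class CommunityConfig:
    """Parameters of the synthetic viral community and its time course.

    Divergences are per-site substitution probabilities applied when deriving
    a child sequence from its ancestor. All proportions live in [0, 1].
    """

    genome_length_bp: int | None = None  # None: drawn uniformly in [44000, 46000]
    gc_fraction: float = 0.63
    n_species: int = 2
    interspecies_divergence: float = 0.12
    n_groups: int = 9
    intragroup_divergence: float = 0.002
    intergroup_divergence: float = 0.02
    genomes_per_group: int = 2
    island_intervals: list[tuple[int, int]] | None = None  # None: one ~3 kb island
    island_divergence: float = 0.30
    sweep_genotype_f0: float = 1e-4
    sweep_f_end: float = 0.5
    timepoints_h: tuple[int, ...] = (0, 72, 168, 336, 672)
    reads_per_sample: int = 5000
    read_length_bp: int = 250
    error_rate: float = 0.005
    background_fraction: float = 0.1
    n_background_genomes: int = 3
    seed: int = 0

    # thresholds the planted structure must respect
    species_identity_threshold: float = 0.95
    genus_identity_threshold: float = 0.70

    def resolved_island_intervals(self, genome_length: int) -> list[tuple[int, int]]:
        if self.island_intervals is not None:
            return [tuple(iv) for iv in self.island_intervals]
        # one ~3 kb island placed mid-genome
        start = int(genome_length * 0.47)
        return [(start, start + 3000)]

    def validate(self) -> None:
        props = {
            "gc_fraction": self.gc_fraction,
            "interspecies_divergence": self.interspecies_divergence,
            "intragroup_divergence": self.intragroup_divergence,
            "intergroup_divergence": self.intergroup_divergence,
            "island_divergence": self.island_divergence,
            "sweep_genotype_f0": self.sweep_genotype_f0,
            "sweep_f_end": self.sweep_f_end,
            "error_rate": self.error_rate,
            "background_fraction": self.background_fraction,
        }
        for name, value in props.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value} outside [0, 1]")
        if self.n_species < 1 or self.n_groups < 1 or self.genomes_per_group < 1:
            raise ConfigError("n_species, n_groups and genomes_per_group must be >= 1")
        if self.genome_length_bp is not None and self.genome_length_bp < 1000:
            raise ConfigError("genome_length_bp too small")
        tp = list(self.timepoints_h)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ConfigError("timepoints_h must be strictly increasing")
        if self.reads_per_sample <= 0:
            raise ConfigError("reads_per_sample must be positive")
        if self.read_length_bp < 20:
            raise ConfigError("read_length_bp too short")

        length = self.genome_length_bp or 44000
        islands = self.resolved_island_intervals(length)
        last_end = 0
        for start, end in sorted(islands):
            if not (0 <= start < end <= length):
                raise ConfigError(f"island interval ({start},{end}) out of genome bounds")
            if start < last_end:
                raise ConfigError("island intervals overlap")
            last_end = end

        # planted identity structure: within-species pairs must stay above the
        # species threshold, between-species pairs inside the genus band.
        # This is a coarse pre-check (layered mutations are not independent,
        # so expectations run slightly low); the generator re-validates the
        # emitted genomes by direct site counting, which is authoritative.
        slack = 0.02
        within = _expected_pair_identity(
            self.intergroup_divergence, self.intergroup_divergence
        ) * _expected_pair_identity(
            self.intragroup_divergence, self.intragroup_divergence
        )
        if within <= self.species_identity_threshold - slack:
            raise ConfigError(
                f"expected within-species identity {within:.3f} <= "
                f"{self.species_identity_threshold} (lower intergroup/intragroup divergence)"
            )
        if self.n_species >= 2:
            island_len = sum(e - s for s, e in islands)
            p_out = _expected_pair_identity(
                self.interspecies_divergence, self.interspecies_divergence
            )
            p_isl = _expected_pair_identity(
                self.island_divergence, self.island_divergence
            )
            between = (
                p_out * (length - island_len) + p_isl * island_len
            ) / length * within  # group/member layers accumulate on top
            if not (self.genus_identity_threshold - slack < between
                    < self.species_identity_threshold + slack):
                raise ConfigError(
                    f"expected between-species identity {between:.3f} outside "
                    f"({self.genus_identity_threshold}, "
                    f"{self.species_identity_threshold})"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["timepoints_h"] = list(self.timepoints_h)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CommunityConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown community config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.timepoints_h = tuple(cfg.timepoints_h)
        return cfg


@dataclass
class RunConfig:
    """End-to-end replay configuration: one synthetic community plus every
    stage threshold, mirroring the published per-stage settings."""

    community: CommunityConfig = field(default_factory=CommunityConfig)
    out_dir: str | None = None
    seed: int = 0
    ponds: tuple[str, ...] = ("amended", "control")

    # recruitment
    min_read_cov: float = 0.70
    seed_k: int = 15
    query_step: int = 2

    # dynamics
    species_identity: float = 0.95  # species-level read filter
    isolate_identity: float = 1.0  # genotype-level read filter
    island_identity_floor: float = 0.70
    island_window_bp: int = 500
    island_ratio_max: float = 0.2
    min_island_len: int = 1000
    min_detect_depth: float = 5.0
    fill_ratio: float = 0.8

    # taxonomy
    run_taxonomy: bool = True
    derep_min_len: int = 43000
    species_threshold: float = 95.0
    genus_threshold: float = 70.0
    n_groups_cut: int | None = None  # None: cut dendrogram at largest gap
    use_planted_orfs: bool = True

    # diversity
    run_diversity: bool = True
    amplicon_reads: int = 2000
    # merged paired-end consensus reads have far lower effective error than
    # single-pass shotgun reads; with 100%-identity phylotyping this matters
    amplicon_error_rate: float = 5e-4
    n_phylotypes: int = 24
    phylotype_divergence: float = 0.03
    rarefaction_depth: int = 1000
    phylotype_filter_k: int = 21
    min_match_frac: float = 0.25
    min_aa_cov: int = 5
    min_mut_codon_count: int = 4
    min_mut_codon_freq: float = 1.0  # percent

    # community distance
    run_distance: bool = True
    sketch_k: int = 21
    sketch_size: int = 10000
    sketch_min_count: int = 2

    def validate(self) -> None:
        self.community.validate()
        for name in (
            "min_read_cov",
            "species_identity",
            "isolate_identity",
            "island_identity_floor",
            "island_ratio_max",
            "fill_ratio",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value} outside [0, 1]")
        if not set(self.ponds) <= {"amended", "control"}:
            raise ConfigError(f"unknown pond labels in {self.ponds}")
        if self.rarefaction_depth > self.amplicon_reads:
            raise ConfigError("rarefaction_depth exceeds amplicon pool size")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["community"] = self.community.to_dict()
        d["ponds"] = list(self.ponds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        community = d.pop("community", {})
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown run config keys: {sorted(unknown)}")
        cfg = cls(community=CommunityConfig.from_dict(community), **d)
        cfg.ponds = tuple(cfg.ponds)
        cfg.community.timepoints_h = tuple(cfg.community.timepoints_h)
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
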