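"""Synthetic community generator: planted structure, read sampling, truth."""

import numpy as np
import pytest

from strainsweep.config import CommunityConfig, ConfigError
from strainsweep.genomes import gc_fraction
from strainsweep.simulate import (CommunityStructureError, community_abundances,
                                  pairwise_site_identity, simulate_amplicon_pool,
                                  simulate_genus, simulate_timecourse,
                                  sweep_trajectory)

from conftest import small_community


class TestSimulateGenus:
    def test_default_scale_genome_length_and_gc(self):
        """Genomes fall in the 44-46 kb, GC 0.63 +/- 0.01 band of the
        emulated isolates."""
        genomes, _ = simulate_genus(CommunityConfig(seed=3))
        community = [g for g in genomes if g.labels["role"] == "community"]
        assert all(44000 <= len(g) <= 46000 for g in community)
        for g in community:
            assert abs(gc_fraction(g.sequence) - 0.63) <= 0.01

    def test_zero_divergence_gives_identical_genomes(self):
        cfg = small_community(seed=1, interspecies_divergence=0.0,
                              intergroup_divergence=0.0,
                              intragroup_divergence=0.0,
                              island_divergence=0.0)
        # identical genomes violate the planted between-species band,
        # which the generator must reject with a diagnostic
        with pytest.raises((CommunityStructureError, ConfigError)):
            simulate_genus(cfg)

    def test_zero_divergence_identity_when_unvalidated(self):
        """With structure checks bypassed (single species), zero divergence
        reproduces the backbone exactly in every group member."""
        cfg = small_community(seed=1, n_species=1, intergroup_divergence=0.0,
                              intragroup_divergence=0.0)
        genomes, _ = simulate_genus(cfg)
        community = [g for g in genomes if g.labels["role"] == "community"]
        first = community[0]
        for g in community[1:]:
            assert pairwise_site_identity(first.codes, g.codes) == 1.0

    def test_planted_identity_bands(self, small_genus):
        """Direct site counting: within-species identity > 0.95,
        between-species in (0.70, 0.95)."""
        genomes, truth = small_genus
        by_id = {g.id: g for g in genomes}
        ids = [g for g, info in truth.genomes.items()
               if info["role"] == "community"]
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                ident = pairwise_site_identity(by_id[a].codes, by_id[b].codes)
                if truth.genomes[a]["species"] == truth.genomes[b]["species"]:
                    assert ident > 0.95
                else:
                    assert 0.70 < ident < 0.95

    def test_island_divergence_by_site_counting(self, small_genus):
        """Inside the planted island, between-species mismatch fraction is
        far above the backbone level and consistent with two branches
        mutated at 0.30 each (with back-substitutions)."""
        genomes, truth = small_genus
        by_id = {g.id: g for g in genomes}
        sweep = by_id[truth.sweep_genotype]
        other = by_id[next(g for g, info in truth.genomes.items()
                           if info["role"] == "community"
                           and info["species"] != truth.genomes[
                               truth.sweep_genotype]["species"])]
        (istart, iend), = truth.island_intervals[sweep.id]
        island_ident = pairwise_site_identity(
            sweep.codes[istart:iend], other.codes[istart:iend])
        outside = np.r_[sweep.codes[:istart], sweep.codes[iend:]] == \
            np.r_[other.codes[:istart], other.codes[iend:]]
        # island mismatch ~ 2*0.30 minus coincidence corrections
        assert 0.40 < island_ident < 0.70
        assert island_ident < float(np.mean(outside)) - 0.10

    def test_orfs_planted_consistently(self, small_genus):
        genomes, _ = small_genus
        community = [g for g in genomes if g.labels["role"] == "community"]
        first = community[0]
        assert first.orfs, "no ORFs planted"
        coding = sum(e - s for s, e, _ in first.orfs) / len(first)
        assert 0.3 < coding < 0.7
        for g in community[1:]:
            assert g.orfs == first.orfs

    def test_same_seed_byte_identical(self):
        cfg = small_community(seed=5)
        g1, t1 = simulate_genus(cfg)
        g2, t2 = simulate_genus(cfg)
        assert [g.sequence for g in g1] == [g.sequence for g in g2]
        assert t1.genomes == t2.genomes

    def test_bad_divergence_rejected(self):
        with pytest.raises((ConfigError, CommunityStructureError)):
            simulate_genus(small_community(seed=0, interspecies_divergence=0.4))
        with pytest.raises((ConfigError, CommunityStructureError)):
            simulate_genus(small_community(seed=0, intergroup_divergence=0.08))


class TestSweepTrajectory:
    def test_logistic_endpoints_and_monotonicity(self):
        tp = [0, 72, 168, 336, 672]
        traj = sweep_trajectory(tp, 1e-4, 0.5)
        assert traj[0] == pytest.approx(1e-4, rel=1e-6)
        assert traj[-1] == pytest.approx(0.5, rel=1e-6)
        assert all(b > a for a, b in zip(traj, traj[1:]))
        # midpoint pinned at the median timepoint: f(168) = amplitude / 2
        assert traj[2] == pytest.approx(0.25, rel=1e-3)

    def test_flat_when_no_sweep(self):
        assert sweep_trajectory([0, 10, 20], 1e-3, 1e-3) == [1e-3] * 3


class TestTimecourse:
    def test_read_counts_exact_and_ids_opaque(self, small_cfg, small_timecourse):
        _, truth, samples = small_timecourse
        assert len(samples) == len(small_cfg.timepoints_h)
        for sample in samples:
            assert len(sample) == small_cfg.reads_per_sample
            assert all(len(seq) == small_cfg.read_length_bp
                       for seq in sample.seqs)
            for rid in sample.ids:
                origin = truth.reads[sample.sample_id][rid]
                assert origin[0] not in rid  # ids encode nothing about origin

    def test_truth_invariants(self, small_timecourse):
        _, truth, _ = small_timecourse
        truth.validate()
        for ab in truth.abundances.values():
            assert sum(ab.values()) == pytest.approx(1.0, abs=1e-12)

    def test_error_free_reads_are_exact_substrings(self):
        cfg = small_community(seed=2, error_rate=0.0, reads_per_sample=150)
        genomes, truth = simulate_genus(cfg)
        samples = simulate_timecourse(genomes, truth, cfg, "amended")
        by_id = {g.id: g for g in genomes}
        from strainsweep.genomes import revcomp
        sample = samples[0]
        for rid, seq in zip(sample.ids, sample.seqs):
            gid, start, end, strand = truth.reads[sample.sample_id][rid]
            source = by_id[gid].sequence[start:end]
            assert seq == (source if strand == "+" else revcomp(source))

    def test_read_counts_binomial_over_seeds(self):
        """Per-genome read counts track planted abundances within 3 binomial
        standard deviations of the expectation, averaged over seeds."""
        n_reads, n_seeds = 2000, 20
        observed = []
        expected_p = None
        for seed in range(n_seeds):
            cfg = small_community(seed=seed, reads_per_sample=n_reads,
                                  n_groups=2, genomes_per_group=1,
                                  background_fraction=0.2)
            genomes, truth = simulate_genus(cfg)
            samples = simulate_timecourse(genomes, truth, cfg, "amended")
            sid = samples[0].sample_id
            ab = truth.abundances[sid]
            expected_p = ab["sp2_g01_m1"]
            count = sum(1 for origin in truth.reads[sid].values()
                        if origin[0] == "sp2_g01_m1")
            observed.append(count)
        mean_expected = expected_p * n_reads
        se = np.sqrt(expected_p * (1 - expected_p) * n_reads / n_seeds)
        assert abs(np.mean(observed) - mean_expected) < 3 * se

    def test_sweep_rare_at_t0(self, small_cfg, small_timecourse):
        """The sweeping genotype starts below the shotgun detection limit."""
        _, truth, samples = small_timecourse
        t0_sample = samples[0].sample_id
        n = sum(1 for origin in truth.reads[t0_sample].values()
                if origin[0] == truth.sweep_genotype)
        assert n <= 2

    def test_rejects_nonpositive_reads(self, small_genus):
        genomes, truth = small_genus
        cfg = small_community(seed=7, reads_per_sample=0)
        with pytest.raises(ValueError):
            simulate_timecourse(genomes, truth, cfg, "amended")


class TestCommunityAbundances:
    def test_partition_and_sweep_mass(self, small_genus):
        _, truth = small_genus
        ab = community_abundances(truth, 0.3, background_fraction=0.1)
        assert sum(ab.values()) == pytest.approx(1.0)
        assert ab[truth.sweep_genotype] == pytest.approx(0.3)


class TestAmpliconPool:
    PHYLO = {"a": "ACGTACGTACGTACGTACGTACGT", "b": "ACGTACGTTCGTACGTACGTACGT"}

    def test_single_phylotype_no_error_all_identical(self):
        pool, _ = simulate_amplicon_pool({"a": self.PHYLO["a"]}, {"a": 1.0},
                                         50, 0.0, seed=1)
        assert set(pool.seqs) == {self.PHYLO["a"]}

    def test_counts_binomial_over_seeds(self):
        counts = []
        n = 1000
        for seed in range(20):
            pool, _ = simulate_amplicon_pool(self.PHYLO, {"a": 0.9, "b": 0.1},
                                             n, 0.0, seed=seed)
            counts.append(sum(1 for s in pool.seqs if s == self.PHYLO["b"]))
        se = np.sqrt(0.9 * 0.1 * n / len(counts))
        assert abs(np.mean(counts) - 100) < 3 * se

    def test_rejects_bad_freqs(self):
        with pytest.raises(ValueError):
            simulate_amplicon_pool(self.PHYLO, {}, 10, 0.0, seed=0)
        with pytest.raises(ValueError):
            simulate_amplicon_pool(self.PHYLO, {"a": 0.5}, 10, 0.0, seed=0)
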