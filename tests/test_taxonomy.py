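"""Dereplication, intergenomic similarity, species/genus and group recovery."""

import numpy as np
import pandas as pd
import pytest

from strainsweep.genomes import Genome, encode, revcomp
from strainsweep.simulate import pairwise_site_identity
from strainsweep.taxonomy import (aai_matrix, assign_species_genus,
                                  cluster_intraspecies_groups,
                                  dereplicate_genomes, intergenomic_similarity,
                                  orf_proteins, pairwise_aai, predict_orfs,
                                  protein_identity, similarity_matrix)

from _oracles import orf_scan_6frame
from conftest import random_seq


def mutate_seq(rng, seq, rate):
    codes = encode(seq)
    hit = rng.random(codes.size) < rate
    n = int(hit.sum())
    codes[hit] = (codes[hit] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    return "".join("ACGT"[c] for c in codes)


class TestDereplicate:
    def test_copy_and_short_genome_dropped(self, rng):
        seq = random_seq(rng, 45000)
        a = Genome(id="A", sequence=seq)
        copy = Genome(id="A_copy", sequence=seq)
        short = Genome(id="B", sequence=random_seq(rng, 40000))
        kept = dereplicate_genomes([a, copy, short])
        assert [g.id for g in kept] == ["A"]

    def test_single_substitution_keeps_both(self, rng):
        seq = random_seq(rng, 44000)
        other = seq[:1000] + ("A" if seq[1000] != "A" else "C") + seq[1001:]
        kept = dereplicate_genomes([Genome(id="A", sequence=seq),
                                    Genome(id="B", sequence=other)])
        assert sorted(g.id for g in kept) == ["A", "B"]

    def test_planted_duplicates_removed(self, rng):
        """10 distinct genomes plus 4 planted copies: exactly 10 retained."""
        distinct = [Genome(id=f"g{i:02d}",
                           sequence=mutate_seq(rng, random_seq(rng, 43500), 0.01))
                    for i in range(10)]
        dups = [Genome(id=f"dup{i}", sequence=distinct[i].sequence)
                for i in range(4)]
        kept = dereplicate_genomes(distinct + dups)
        # one representative per identical class survives
        assert len(kept) == 10
        assert len({g.sequence for g in kept}) == 10

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dereplicate_genomes([])


class TestIntergenomicSimilarity:
    def test_self_similarity_100(self, rng):
        g = Genome(id="g", sequence=random_seq(rng, 20000))
        assert intergenomic_similarity(g, g).intergenomic_sim == 100.0

    def test_four_percent_divergence(self, rng):
        """A full-length homolog with ~4% planted substitutions scores an
        intergenomic similarity matching direct site counting within 0.5."""
        seq = random_seq(rng, 20000)
        hom = mutate_seq(rng, seq, 0.04)
        a, b = Genome(id="a", sequence=seq), Genome(id="b", sequence=hom)
        planted = 100 * pairwise_site_identity(a.codes, b.codes)
        sim = intergenomic_similarity(a, b)
        assert sim.intergenomic_sim == pytest.approx(planted, abs=0.5)
        assert sim.aligned_frac_a > 0.99 and sim.aligned_frac_b > 0.99

    def test_unrelated_genomes_near_zero(self, rng):
        a = Genome(id="a", sequence=random_seq(rng, 15000))
        b = Genome(id="b", sequence=random_seq(rng, 15000))
        sim = intergenomic_similarity(a, b)
        assert sim.intergenomic_sim < 5.0
        assert sim.aligned_frac_a < 0.05

    def test_reciprocal_within_one_point(self, rng):
        seq = random_seq(rng, 18000)
        hom = mutate_seq(rng, seq, 0.05)
        a, b = Genome(id="a", sequence=seq), Genome(id="b", sequence=hom)
        fwd = intergenomic_similarity(a, b).intergenomic_sim
        rev = intergenomic_similarity(b, a).intergenomic_sim
        assert abs(fwd - rev) <= 1.0


class TestSpeciesGenus:
    def _matrix(self, values):
        ids = [f"g{i}" for i in range(len(values))]
        return pd.DataFrame(values, index=ids, columns=ids, dtype=float)

    def test_pair_at_96_same_species(self):
        tax = assign_species_genus(self._matrix([[100, 96], [96, 100]]))
        assert tax["g0"].species_id == tax["g1"].species_id
        assert tax["g0"].genus_id == tax["g1"].genus_id

    def test_pair_at_85_same_genus_different_species(self):
        tax = assign_species_genus(self._matrix([[100, 85], [85, 100]]))
        assert tax["g0"].genus_id == tax["g1"].genus_id
        assert tax["g0"].species_id != tax["g1"].species_id

    def test_pair_at_60_different_genus(self):
        tax = assign_species_genus(self._matrix([[100, 60], [60, 100]]))
        assert tax["g0"].genus_id != tax["g1"].genus_id

    def test_input_order_invariance(self):
        m = self._matrix([[100, 96, 60], [96, 100, 60], [60, 60, 100]])
        shuffled = m.loc[["g2", "g0", "g1"], ["g2", "g0", "g1"]]
        t1 = assign_species_genus(m)
        t2 = assign_species_genus(shuffled)
        for gid in m.index:
            assert t1[gid].species_id == t2[gid].species_id
            assert t1[gid].genus_id == t2[gid].genus_id

    def test_simulated_community_two_species_one_genus(self, small_genus):
        genomes, truth = small_genus
        community = [g for g in genomes if g.labels["role"] == "community"]
        sim = similarity_matrix(community)
        tax = assign_species_genus(sim)
        genera = {a.genus_id for a in tax.values()}
        species = {a.species_id for a in tax.values()}
        assert len(genera) == 1 and len(species) == 2
        for gid, a in tax.items():
            for hid, b in tax.items():
                same_truth = truth.genomes[gid]["species"] == \
                    truth.genomes[hid]["species"]
                assert (a.species_id == b.species_id) == same_truth

    def test_asymmetric_matrix_rejected(self):
        m = self._matrix([[100, 96], [80, 100]])
        with pytest.raises(ValueError):
            assign_species_genus(m)


class TestPredictOrfs:
    def _stop_rich(self, rng, length):
        # stop codons in every frame: TAA TAG TGA repeated
        return ("TAATAGTGA" * (length // 9 + 1))[:length]

    def test_planted_orf_recovered_exactly(self, rng):
        flank1 = self._stop_rich(rng, 300)
        flank2 = self._stop_rich(rng, 300)
        body = "ATG" + "GCT" * 198 + "TAA"  # 600 nt ORF
        genome = Genome(id="g", sequence=flank1 + body + flank2)
        orfs = predict_orfs(genome)
        assert (300, 900, "+") in orfs
        assert orfs == orf_scan_6frame(genome.sequence) or \
            set(orfs) <= set(orf_scan_6frame(genome.sequence))

    def test_all_stop_sequence_has_no_orfs(self, rng):
        genome = Genome(id="g", sequence=self._stop_rich(rng, 600))
        assert predict_orfs(genome) == []

    def test_reverse_complement_flips_strands(self, rng):
        flank1 = self._stop_rich(rng, 300)
        flank2 = self._stop_rich(rng, 303)
        body = "ATG" + "GAT" * 150 + "TGA"
        seq = flank1 + body + flank2
        fwd = predict_orfs(Genome(id="f", sequence=seq))
        rev = predict_orfs(Genome(id="r", sequence=revcomp(seq)))
        length = len(seq)
        flipped = sorted((length - e, length - s,
                          "-" if strand == "+" else "+")
                         for s, e, strand in fwd)
        assert flipped == rev

    def test_brute_force_frame_scan_agreement(self, rng):
        """Candidate ORFs (before overlap resolution) match the exhaustive
        6-frame oracle on random sequences."""
        for seed in range(5):
            local = np.random.default_rng(seed)
            seq = random_seq(local, 3000)
            genome = Genome(id="g", sequence=seq)
            called = predict_orfs(genome, min_len=150)
            oracle = orf_scan_6frame(seq, min_len=150)
            assert set(called) <= set(oracle)


class TestAAI:
    def test_identical_sets_100(self):
        prots = ["MKLV" * 10, "MAACDEF" * 5]
        aai, pairs = pairwise_aai(prots, prots)
        assert aai == 100.0 and pairs == 2

    def test_hand_example_single_substitution(self):
        """One 10-residue protein with one substitution (90%), one identical
        (100%): AAI is the mean, 95%."""
        a = ["MKLVAAGHIW", "MPPPPPPPPP"]
        b = ["MKLVAAGHIV", "MPPPPPPPPP"]
        aai, pairs = pairwise_aai(a, b)
        assert pairs == 2
        assert aai == pytest.approx(95.0)

    def test_disjoint_proteins_missing(self):
        aai, pairs = pairwise_aai(["MKKKKKKKKK"], ["WCCCCCCCCC"])
        assert aai is None and pairs == 0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            pairwise_aai([], ["MKL"])

    def test_protein_identity_unequal_lengths(self):
        assert protein_identity("MKLVA", "MKLV") == pytest.approx(0.8)


class TestGroupClustering:
    def test_identical_genomes_one_group(self, rng):
        seq = random_seq(rng, 3000)
        genomes = [Genome(id=f"g{i}", sequence=seq) for i in range(4)]
        aai = pd.DataFrame(100.0, index=[g.id for g in genomes],
                           columns=[g.id for g in genomes])
        groups = cluster_intraspecies_groups(aai, genomes)
        assert len({a.group_id for a in groups.values()}) == 1

    def test_reference_is_longest_genome(self, rng):
        a = Genome(id="a", sequence=random_seq(rng, 45000))
        b = Genome(id="b", sequence=random_seq(rng, 45010))
        aai = pd.DataFrame(100.0, index=["a", "b"], columns=["a", "b"])
        groups = cluster_intraspecies_groups(aai, [a, b], n_groups=1)
        assert groups["b"].is_reference and not groups["a"].is_reference

    def test_planted_groups_recovered(self, small_genus):
        """Average-linkage Bray-Curtis clustering of the AAI matrix recovers
        the planted intra-species groups with perfect membership."""
        genomes, truth = small_genus
        members = [g for g in genomes
                   if truth.genomes.get(g.id, {}).get("species") == "species_1"]
        aai = aai_matrix(members)
        groups = cluster_intraspecies_groups(aai, members)
        for a in members:
            for b in members:
                same_truth = truth.genomes[a.id]["group"] == \
                    truth.genomes[b.id]["group"]
                same_called = groups[a.id].group_id == groups[b.id].group_id
                assert same_called == same_truth

    def test_missing_aai_entry_rejected(self, rng):
        genomes = [Genome(id="a", sequence=random_seq(rng, 1000)),
                   Genome(id="b", sequence=random_seq(rng, 1000))]
        aai = pd.DataFrame([[100.0, np.nan], [np.nan, 100.0]],
                           index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            cluster_intraspecies_groups(aai, genomes)


class TestOrfProteins:
    def test_translation_trims_stop(self):
        genome = Genome(id="g", sequence="ATGGCTGCTTAA",
                        orfs=[(0, 12, "+")])
        assert orf_proteins(genome) == ["MAA"]

    def test_reverse_strand_orf(self):
        fwd = "ATGGCTGCTTAA"
        genome = Genome(id="g", sequence=revcomp(fwd), orfs=[(0, 12, "-")])
        assert orf_proteins(genome) == ["MAA"]
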