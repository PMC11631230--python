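"""Amplicon phylotype diversity and codon-level variant statistics.

Phylotypes are exact-sequence clusters (100% identity and coverage): exact
duplicates collapse, and a shorter read that is an exact substring of a
longer retained read joins that phylotype. Diversity uses the natural-log
Shannon index on rarefied counts.

Codon variant counting follows the DiversiTools conventions: per-codon read
counts from reads spanning all three codon positions, a coverage floor
(min_aa_cov), and an alternative codon is only counted when its read count
and percent frequency both reach their thresholds; counted alternatives are
classified synonymous/nonsynonymous against the reference codon under the
standard genetic code.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.stats import entropy

from .genomes import Genome


@dataclass
class PhylotypeTable:
    locus_id: str
    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)  # phylotype seq -> count

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    def frequencies(self) -> dict[str, float]:
        total = self.n_total
        return {seq: c / total for seq, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(
            [{"locus_id": self.locus_id, "sample_id": self.sample_id,
              "phylotype": seq, "count": c} for seq, c in rows]
        )


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def reference_kmer_set(genomes: list[Genome], k: int = 21) -> set[str]:
    from .genomes import revcomp

    kmers: set[str] = set()
    for g in genomes:
        kmers |= _kmer_set(g.sequence, k)
        kmers |= _kmer_set(revcomp(g.sequence), k)
    return kmers


def phylotype_profile(reads, reference_genomes: list[Genome] | None,
                      min_match_frac: float = 0.25, k: int = 21,
                      locus_id: str = "locus", sample_id: str = "",
                      reference_kmers: set[str] | None = None,
                      ) -> PhylotypeTable:
    """Collapse amplicon reads into exact phylotypes after a reference screen.

    The screen keeps reads whose fraction of k-mers (k=21) contained in the
    reference genomes' k-mer set reaches ``min_match_frac`` — a
    deterministic stand-in for the published similarity-search filter whose
    role is to remove spurious sequences. Surviving reads collapse at 100%
    identity and coverage with the longest read as representative.
    """
    from .simulate import SampleReads

    if isinstance(reads, SampleReads):
        seqs = reads.seqs
        sample_id = sample_id or reads.sample_id
    else:
        seqs = list(reads)

    if reference_kmers is None and reference_genomes:
        reference_kmers = reference_kmer_set(reference_genomes, k)

    survivors: list[str] = []
    for seq in seqs:
        seq = seq.upper()
        if reference_kmers is not None:
            kmers = _kmer_set(seq, k)
            if not kmers:
                continue
            frac = sum(1 for km in kmers if km in reference_kmers) / len(kmers)
            if frac < min_match_frac:
                continue
        survivors.append(seq)

    table = PhylotypeTable(locus_id=locus_id, sample_id=sample_id)
    if not survivors:
        return table
    unique = Counter(survivors)
    reps: list[str] = []
    counts: dict[str, int] = {}
    for seq in sorted(unique, key=lambda s: (-len(s), s)):
        home = next((r for r in reps if seq in r), None)
        if home is None:
            reps.append(seq)
            counts[seq] = unique[seq]
        else:
            counts[home] += unique[seq]
    table.counts = counts
    return table


def rarefy(table: PhylotypeTable, n: int, seed: int) -> PhylotypeTable:
    """Subsample n reads uniformly without replacement (deterministic per
    seed); phylotypes drawn zero times drop out."""
    total = table.n_total
    if n > total:
        raise ValueError(f"cannot rarefy {total} reads to {n}")
    rng = np.random.default_rng(seed)
    seqs = sorted(table.counts)
    counts = np.array([table.counts[s] for s in seqs])
    sub = rng.multivariate_hypergeometric(counts, n)
    return PhylotypeTable(
        locus_id=table.locus_id, sample_id=table.sample_id,
        counts={s: int(c) for s, c in zip(seqs, sub) if c > 0},
    )


def shannon_index(table: PhylotypeTable | dict[str, int] | list[int]) -> float:
    """H' = -sum p_i ln p_i over phylotype frequencies (natural log)."""
    if isinstance(table, PhylotypeTable):
        counts = list(table.counts.values())
    elif isinstance(table, dict):
        counts = list(table.values())
    else:
        counts = list(table)
    counts = [c for c in counts if c > 0]
    if not counts:
        raise ValueError("empty phylotype table")
    return float(entropy(counts))


@dataclass
class CodonRecord:
    codon_index: int
    coverage: int
    ref_codon: str
    alt_counts: dict[str, int]  # counted alternatives only
    syn_count: int
    nonsyn_count: int


@dataclass
class CodonVariantTable:
    orf_id: str
    records: list[CodonRecord] = field(default_factory=list)

    @property
    def syn_total(self) -> int:
        return sum(r.syn_count for r in self.records)

    @property
    def nonsyn_total(self) -> int:
        return sum(r.nonsyn_count for r in self.records)

    @property
    def pn_fraction(self) -> float | None:
        """pN / (pN + pS); None when no variants were counted."""
        total = self.syn_total + self.nonsyn_total
        if total == 0:
            return None
        return self.nonsyn_total / total

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            for alt, count in sorted(r.alt_counts.items()):
                rows.append({
                    "orf_id": self.orf_id, "codon_index": r.codon_index,
                    "coverage": r.coverage, "ref_codon": r.ref_codon,
                    "alt_codon": alt, "alt_count": count,
                    "synonymous": str(Seq(alt).translate())
                    == str(Seq(r.ref_codon).translate()),
                })
        return pd.DataFrame(rows)


def codon_variant_counts(orf_seq: str, segments: list[tuple[int, str]],
                         min_aa_cov: int = 5, min_mut_codon_count: int = 4,
                         min_mut_codon_freq: float = 1.0,
                         orf_id: str = "orf") -> CodonVariantTable:
    """Count synonymous/nonsynonymous codon variants in an in-frame pileup.

    ``segments`` are (offset, sequence) pairs giving each read's aligned
    portion relative to the ORF start (offset 0 = first base of the first
    codon); only reads spanning all three positions of a codon contribute
    to its coverage. ``min_mut_codon_freq`` is a percentage.
    """
    orf_seq = orf_seq.upper()
    if len(orf_seq) % 3:
        raise ValueError("ORF length not divisible by 3")
    n_codons = len(orf_seq) // 3
    per_codon: list[Counter] = [Counter() for _ in range(n_codons)]
    for offset, seq in segments:
        seq = seq.upper()
        first = max(0, -(-offset // 3))  # first codon fully covered
        last = (offset + len(seq)) // 3  # exclusive
        for ci in range(max(first, 0), min(last, n_codons)):
            start = 3 * ci - offset
            per_codon[ci][seq[start:start + 3]] += 1

    table = CodonVariantTable(orf_id=orf_id)
    for ci in range(n_codons):
        tally = per_codon[ci]
        coverage = sum(tally.values())
        if coverage < min_aa_cov:
            continue
        ref = orf_seq[3 * ci:3 * ci + 3]
        ref_aa = str(Seq(ref).translate())
        alts: dict[str, int] = {}
        syn = nonsyn = 0
        for codon, count in tally.items():
            if codon == ref or "N" in codon:
                continue
            if count < min_mut_codon_count:
                continue
            if 100.0 * count / coverage < min_mut_codon_freq:
                continue
            alts[codon] = count
            if str(Seq(codon).translate()) == ref_aa:
                syn += count
            else:
                nonsyn += count
        if alts:
            table.records.append(CodonRecord(
                codon_index=ci, coverage=coverage, ref_codon=ref,
                alt_counts=alts, syn_count=syn, nonsyn_count=nonsyn,
            ))
    return table


def orf_pileup(hits, reads_by_id: dict[str, str], genome: Genome,
               orf: tuple[int, int, str]) -> list[tuple[int, str]]:
    """Build in-frame (offset, sequence) segments for one forward-strand ORF
    from per-reference hits (reverse-strand hits are re-oriented)."""
    from .genomes import revcomp

    start, end, strand = orf
    if strand != "+":
        raise ValueError("pileups are built for forward-strand ORFs")
    segments: list[tuple[int, str]] = []
    for h in hits:
        if h.genome_id != genome.id or h.g_end <= start or h.g_start >= end:
            continue
        read = reads_by_id[h.read_id].upper()
        if h.strand == "-":
            read = revcomp(read)
        # the hit's aligned span maps 1:1 (ungapped); recover the read part
        # that sits on the genome interval [g_start, g_end)
        aligned = read[-h.aligned_nt:] if h.strand == "-" else read[:h.aligned_nt]
        # for trimmed alignments the aligned read interval is not recorded in
        # the hit; reads are only usable when fully aligned
        if h.aligned_nt != len(read):
            continue
        segments.append((h.g_start - start, aligned))
    return segments
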