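"""Viral genome dereplication, species/genus assignment and group clustering.

The clustering chain mirrors standard viral taxonomy practice: VIRIDIC-style
intergenomic similarity (nucleotide identity weighted by the smaller aligned
genome fraction) with the ICTV 95%/70% species/genus thresholds applied as
connected components, then intra-species groups from average-linkage
clustering of Bray-Curtis dissimilarities over rows of the reciprocal-
best-match amino-acid-identity (AAI) matrix. Each group's reference is its
largest genome (ties: fewest ambiguous bases, then smallest id).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .align import SeedIndex, best_segment_on_diagonal
from .genomes import Genome, encode, revcomp

DEFAULT_FRAGMENT = 1000
DEFAULT_FRAGMENT_STEP = 500


@dataclass
class PairwiseSimilarity:
    genome_a: str
    genome_b: str
    aligned_frac_a: float
    aligned_frac_b: float
    identity: float  # matches / aligned columns, in [0, 1]
    intergenomic_sim: float  # identity * min(aligned fracs), percent scale


@dataclass
class TaxonAssignment:
    genome_id: str
    genus_id: str | None = None
    species_id: str | None = None
    group_id: str | None = None
    is_reference: bool = False


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total, cursor = 0, -1
    for start, end in sorted(intervals):
        if start > cursor:
            total += end - start
            cursor = end
        elif end > cursor:
            total += end - cursor
            cursor = end
    return total


def _target_index(genome: Genome, k: int, index_step: int,
                  cache: dict | None) -> SeedIndex:
    if cache is None:
        return SeedIndex([genome], k=k, step=index_step)
    key = (genome.id, k, index_step)
    if key not in cache:
        cache[key] = SeedIndex([genome], k=k, step=index_step)
    return cache[key]


def intergenomic_similarity(g1: Genome, g2: Genome,
                            fragment: int = DEFAULT_FRAGMENT,
                            step: int = DEFAULT_FRAGMENT_STEP,
                            k: int = 15, query_step: int = 2,
                            index_step: int = 3,
                            index_cache: dict | None = None,
                            ) -> PairwiseSimilarity:
    """VIRIDIC-style whole-genome similarity.

    The shorter genome is fragmented into overlapping windows; each window
    is placed on the other genome by ungapped local alignment. Identity is
    the alignment-length-weighted mean over placed windows; aligned
    fractions are the covered proportions of each genome. ``index_cache``
    lets matrix-level callers reuse per-genome seed indexes.
    """
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("empty genome")
    if g1.id == g2.id and g1.sequence == g2.sequence:
        return PairwiseSimilarity(g1.id, g2.id, 1.0, 1.0, 1.0, 100.0)
    query, target = (g1, g2) if len(g1) <= len(g2) else (g2, g1)
    index = _target_index(target, k, index_step, index_cache)
    tcodes = target.codes
    starts = list(range(0, max(1, len(query) - fragment + 1), step))
    if starts and starts[-1] + fragment < len(query):
        starts.append(len(query) - fragment)

    matches_total = 0
    columns_total = 0
    q_cov: list[tuple[int, int]] = []
    t_cov: list[tuple[int, int]] = []
    from .genomes import decode, revcomp_codes

    for qs in starts:
        window = query.sequence[qs:qs + fragment]
        fwd = encode(window)
        rc = revcomp_codes(fwd)
        best = None
        for strand, codes, seq in (("+", fwd, window), ("-", rc, decode(rc))):
            for _, offset in sorted(index.candidate_diagonals(seq, query_step)):
                seg = best_segment_on_diagonal(codes, tcodes, offset)
                if seg is None:
                    continue
                score, m, t_start, t_end, r_start, r_end = seg
                cand = (score, m, t_start, t_end, r_start, r_end, strand)
                if best is None or cand[0] > best[0]:
                    best = cand
        if best is None:
            continue
        _, m, t_start, t_end, r_start, r_end, strand = best
        matches_total += m
        columns_total += t_end - t_start
        t_cov.append((t_start, t_end))
        if strand == "+":
            q_cov.append((qs + r_start, qs + r_end))
        else:
            wlen = len(window)
            q_cov.append((qs + wlen - r_end, qs + wlen - r_start))

    if columns_total == 0:
        sim = PairwiseSimilarity(g1.id, g2.id, 0.0, 0.0, 0.0, 0.0)
        return sim
    identity = matches_total / columns_total
    frac_q = min(1.0, _union_length(q_cov) / len(query))
    frac_t = min(1.0, _union_length(t_cov) / len(target))
    frac_1, frac_2 = (frac_q, frac_t) if query is g1 else (frac_t, frac_q)
    return PairwiseSimilarity(
        genome_a=g1.id, genome_b=g2.id,
        aligned_frac_a=frac_1, aligned_frac_b=frac_2,
        identity=identity,
        intergenomic_sim=100.0 * identity * min(frac_1, frac_2),
    )


def similarity_matrix(genomes: list[Genome], **kwargs) -> pd.DataFrame:
    """Symmetric intergenomic-similarity matrix (percent; diagonal 100)."""
    ids = [g.id for g in genomes]
    kwargs.setdefault("index_cache", {})
    mat = pd.DataFrame(100.0, index=ids, columns=ids, dtype=float)
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            sim = intergenomic_similarity(genomes[i], genomes[j], **kwargs)
            mat.iloc[i, j] = sim.intergenomic_sim
            mat.iloc[j, i] = sim.intergenomic_sim
    return mat


def dereplicate_genomes(genomes: list[Genome], min_len: int = 43000,
                        min_id: float = 1.0, min_aligned_frac: float = 0.8,
                        ) -> list[Genome]:
    """Drop short genomes, then collapse redundant ones (longest-first).

    A genome is redundant when it aligns to an already-retained, at least
    as long genome at identity >= min_id over >= min_aligned_frac of its
    own length.
    """
    if not genomes:
        raise ValueError("empty genome set")
    candidates = [g for g in genomes if len(g) >= min_len]
    candidates.sort(key=lambda g: (-len(g), g.id))
    cache: dict = {}
    retained: list[Genome] = []
    for g in candidates:
        redundant = False
        for r in retained:
            if min_id >= 1.0 and len(g) == len(r):
                # exact-identity redundancy between equal-length genomes
                # reduces to sequence equality: any substitution leaves the
                # aligned-weighted mean identity below 1
                if g.sequence == r.sequence:
                    redundant = True
                    break
                continue
            sim = intergenomic_similarity(g, r, index_cache=cache)
            own_frac = sim.aligned_frac_a if sim.genome_a == g.id else sim.aligned_frac_b
            if sim.identity >= min_id and own_frac >= min_aligned_frac:
                redundant = True
                break
        if not redundant:
            retained.append(g)
    return retained


def assign_species_genus(sim: pd.DataFrame, species_thr: float = 95.0,
                         genus_thr: float = 70.0) -> dict[str, TaxonAssignment]:
    """Genera: connected components at similarity >= genus threshold;
    species: components within a genus at similarity > species threshold."""
    if list(sim.index) != list(sim.columns):
        raise ValueError("similarity matrix must be square with matching labels")
    if not np.allclose(sim.values, sim.values.T, atol=1e-6):
        raise ValueError("similarity matrix must be symmetric")
    ids = sorted(sim.index)
    m = sim.loc[ids, ids].values

    def components(adj: np.ndarray) -> np.ndarray:
        n, labels = connected_components(csr_matrix(adj), directed=False)
        # canonical labels ordered by first member
        remap, nxt = {}, 1
        out = np.zeros_like(labels)
        for i, lab in enumerate(labels):
            if lab not in remap:
                remap[lab] = nxt
                nxt += 1
            out[i] = remap[lab]
        return out

    genus_labels = components(m >= genus_thr)
    species_labels = np.zeros(len(ids), dtype=int)
    nxt = 1
    for gl in sorted(set(genus_labels)):
        members = np.nonzero(genus_labels == gl)[0]
        sub = m[np.ix_(members, members)] > species_thr
        np.fill_diagonal(sub, True)
        sub_labels = components(sub)
        for local, idx in zip(sub_labels, members):
            species_labels[idx] = nxt + local - 1
        nxt += sub_labels.max()

    return {
        gid: TaxonAssignment(genome_id=gid,
                             genus_id=f"genus_{genus_labels[i]}",
                             species_id=f"species_{species_labels[i]}")
        for i, gid in enumerate(ids)
    }


def predict_orfs(genome: Genome, min_len: int = 300) -> list[tuple[int, int, str]]:
    """Maximal start-to-stop ORFs >= min_len nt on both strands.

    Intervals are forward-genome coordinates including the stop codon;
    overlapping calls are resolved longest-first.
    """
    length = len(genome)
    candidates: list[tuple[int, int, str]] = []
    for strand in "+-":
        seq = genome.sequence if strand == "+" else revcomp(genome.sequence)
        for frame in range(3):
            pos = frame
            orf_start = None
            while pos + 3 <= len(seq):
                codon = seq[pos:pos + 3]
                if orf_start is None:
                    if codon == "ATG":
                        orf_start = pos
                elif codon in ("TAA", "TAG", "TGA"):
                    end = pos + 3
                    if end - orf_start >= min_len:
                        if strand == "+":
                            candidates.append((orf_start, end, "+"))
                        else:
                            candidates.append((length - end, length - orf_start, "-"))
                    orf_start = None
                pos += 3
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    chosen: list[tuple[int, int, str]] = []
    occupied = np.zeros(length, dtype=bool)
    for start, end, strand in candidates:
        if not occupied[start:end].any():
            chosen.append((start, end, strand))
            occupied[start:end] = True
    chosen.sort()
    return chosen


def orf_proteins(genome: Genome, orfs: list[tuple[int, int, str]] | None = None
                 ) -> list[str]:
    """Translate ORFs (standard code), trimming the terminal stop."""
    proteins = []
    for start, end, strand in (orfs if orfs is not None else genome.orfs):
        nt = genome.sequence[start:end]
        if strand == "-":
            nt = revcomp(nt)
        aa = str(Seq(nt).translate())
        proteins.append(aa[:-1] if aa.endswith("*") else aa)
    return proteins


def protein_identity(a: str, b: str) -> float:
    """Global identity of two proteins (match/mismatch; indel-free pairs
    reduce to direct site comparison, others use edit distance)."""
    if not a or not b:
        return 0.0
    if len(a) == len(b):
        arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
        arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
        return float(np.mean(arr_a == arr_b))
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return max(0.0, 1.0 - dist / max(len(a), len(b)))


def pairwise_aai(proteins_a: list[str], proteins_b: list[str],
                 ) -> tuple[float | None, int]:
    """Mean amino-acid identity over reciprocal best matches (percent).

    Returns (AAI, retained pair count); AAI is None when no reciprocal
    pairs exist.
    """
    if not proteins_a or not proteins_b:
        raise ValueError("empty ORF set")
    na, nb = len(proteins_a), len(proteins_b)
    ident = np.zeros((na, nb))
    for i, pa in enumerate(proteins_a):
        for j, pb in enumerate(proteins_b):
            ident[i, j] = protein_identity(pa, pb)
    best_a = ident.argmax(axis=1)
    best_b = ident.argmax(axis=0)
    pairs = [(i, best_a[i]) for i in range(na)
             if best_b[best_a[i]] == i and ident[i, best_a[i]] > 0]
    if not pairs:
        return None, 0
    values = [100.0 * ident[i, j] for i, j in pairs]
    return float(np.mean(values)), len(pairs)


def aai_matrix(genomes: list[Genome],
               orfs_by_genome: dict[str, list[tuple[int, int, str]]] | None = None,
               ) -> pd.DataFrame:
    ids = [g.id for g in genomes]
    prots = {
        g.id: orf_proteins(g, orfs_by_genome.get(g.id) if orfs_by_genome else None)
        for g in genomes
    }
    mat = pd.DataFrame(100.0, index=ids, columns=ids, dtype=float)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            aai, _ = pairwise_aai(prots[ids[i]], prots[ids[j]])
            value = np.nan if aai is None else aai
            mat.iloc[i, j] = value
            mat.iloc[j, i] = value
    return mat


def cluster_intraspecies_groups(aai: pd.DataFrame, genomes: list[Genome],
                                n_groups: int | None = None,
                                cut_height: float | None = None,
                                ) -> dict[str, TaxonAssignment]:
    """Intra-species groups from the AAI matrix.

    Dissimilarity is Bray-Curtis between rows of the AAI matrix; clustering
    is average linkage. The tree is cut at a requested group count, at a
    requested height, or (default) at the largest gap between successive
    merge heights. One reference per group: longest genome, ties broken by
    fewest ambiguous bases then smallest id.
    """
    if aai.isna().any().any():
        bad = [(r, c) for r in aai.index for c in aai.columns
               if pd.isna(aai.loc[r, c])]
        raise ValueError(f"missing AAI entries, e.g. {bad[0]}")
    ids = sorted(aai.index)
    by_id = {g.id: g for g in genomes}
    if len(ids) == 1:
        labels = np.array([1])
    else:
        rows = aai.loc[ids, ids].values
        n = len(ids)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                a, b = rows[i], rows[j]
                dist[i, j] = dist[j, i] = np.abs(a - b).sum() / (a + b).sum()
        z = linkage(squareform(dist, checks=False), method="average")
        heights = z[:, 2]
        if n_groups is not None:
            labels = fcluster(z, t=n_groups, criterion="maxclust")
        elif cut_height is not None:
            labels = fcluster(z, t=cut_height, criterion="distance")
        elif heights[-1] <= 1e-12:
            labels = np.ones(n, dtype=int)
        else:
            padded = np.concatenate(([0.0], np.sort(heights)))
            gaps = np.diff(padded)
            cut_at = int(np.argmax(gaps))
            threshold = (padded[cut_at] + padded[cut_at + 1]) / 2.0
            labels = fcluster(z, t=threshold, criterion="distance")

    # canonical group ids ordered by first member
    remap: dict[int, int] = {}
    assignments: dict[str, TaxonAssignment] = {}
    for gid, lab in zip(ids, labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        assignments[gid] = TaxonAssignment(genome_id=gid,
                                           group_id=f"group_{remap[lab]:02d}")
    for group in sorted({a.group_id for a in assignments.values()}):
        members = [gid for gid, a in assignments.items() if a.group_id == group]
        ref = min(members, key=lambda gid: (-len(by_id[gid]),
                                            by_id[gid].n_ambiguous(), gid))
        assignments[ref].is_reference = True
    return assignments


def assignments_to_frame(assignments: dict[str, TaxonAssignment]) -> pd.DataFrame:
    rows = [{
        "genome_id": gid,
        "genus": a.genus_id,
        "species": a.species_id,
        "group": a.group_id,
        "is_reference": a.is_reference,
    } for gid, a in sorted(assignments.items())]
    return pd.DataFrame(rows)
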