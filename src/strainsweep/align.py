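"""Ungapped seed-and-extend read placement.

Exact k-mer seeds (default k=15) locate candidate diagonals on both strands;
each candidate diagonal is scored by the maximal-scoring ungapped local
segment (match +1, mismatch -1), found with a vectorised maximum-subarray
scan. Because scoring is ungapped, identity = matches / alignment columns
and the aligned read span maps 1:1 onto the genome span.

Tie-breaking is fully deterministic: higher score, then more aligned
columns, then higher identity, then lexicographically smaller genome id,
then forward before reverse strand, then the smaller genome start. Within a
diagonal the maximum-subarray scan itself prefers the smallest end and then
the smallest start among equal-scoring segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomes import Genome, encode, revcomp_codes

DEFAULT_SEED_K = 15


@dataclass
class RecruitmentHit:
    """One read placed on one genome (ungapped, 0-based half-open coords)."""

    read_id: str
    genome_id: str
    g_start: int
    g_end: int
    strand: str
    identity: float
    read_cov: float
    aligned_nt: int
    score: int = 0

    def __post_init__(self):
        if self.g_start >= self.g_end:
            raise ValueError(f"hit {self.read_id}: empty genome interval")
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.read_cov <= 1.0):
            raise ValueError(f"hit {self.read_id}: identity/read_cov outside [0,1]")


class SeedIndex:
    """Exact k-mer index over one or more genomes.

    ``step`` subsamples indexed genome positions; a query k-mer whose exact
    match starts within an error-free stretch of length >= k + step - 1 is
    guaranteed to hit the index.
    """

    def __init__(self, genomes: list[Genome], k: int = DEFAULT_SEED_K, step: int = 1):
        if k < 4:
            raise ValueError("seed k too small")
        self.k = k
        self.step = step
        self.genomes = list(genomes)
        self.codes = [g.codes for g in self.genomes]
        self.ids = [g.id for g in self.genomes]
        index: dict[str, list[tuple[int, int]]] = {}
        for gi, g in enumerate(self.genomes):
            seq = g.sequence
            for pos in range(0, len(seq) - k + 1, step):
                index.setdefault(seq[pos:pos + k], []).append((gi, pos))
        self.index = index

    def candidate_diagonals(self, read_seq: str, query_step: int = 1
                            ) -> set[tuple[int, int]]:
        """(genome_idx, offset) pairs where offset places read base 0."""
        k = self.k
        out: set[tuple[int, int]] = set()
        get = self.index.get
        for i in range(0, len(read_seq) - k + 1, query_step):
            hits = get(read_seq[i:i + k])
            if hits:
                for gi, pos in hits:
                    out.add((gi, pos - i))
        return out


def best_segment_on_diagonal(read_codes: np.ndarray, genome_codes: np.ndarray,
                             offset: int) -> tuple[int, int, int, int, int, int] | None:
    """Maximal-scoring ungapped segment of the read placed at ``offset``.

    Returns (score, matches, g_start, g_end, r_start, r_end) or None when the
    diagonal leaves no overlap. Ties prefer the smallest end then the
    smallest start.
    """
    a = max(0, offset)
    b = min(genome_codes.size, offset + read_codes.size)
    if b - a < 1:
        return None
    r0 = a - offset
    eq = genome_codes[a:b] == read_codes[r0:r0 + (b - a)]
    scores = np.where(eq, 1, -1)
    csum = np.concatenate(([0], np.cumsum(scores)))
    runmin = np.minimum.accumulate(csum)
    gains = csum[1:] - runmin[:-1]
    j = int(np.argmax(gains))          # first best end
    score = int(gains[j])
    if score <= 0:
        return None
    start = int(np.argmax(csum == runmin[j]))  # first prefix attaining the min
    end = j + 1
    length = end - start
    matches = (length + score) // 2
    return score, matches, a + start, a + end, r0 + start, r0 + end


def _hit_sort_key(hit: RecruitmentHit):
    return (-hit.score, -hit.aligned_nt, -hit.identity, hit.genome_id,
            hit.strand, hit.g_start)


def _evaluate_candidates(read_id: str, read_len: int,
                         fwd_codes: np.ndarray, rc_codes: np.ndarray,
                         index: SeedIndex,
                         fwd_diags: set[tuple[int, int]],
                         rc_diags: set[tuple[int, int]]) -> list[RecruitmentHit]:
    hits: list[RecruitmentHit] = []
    for strand, codes, diags in (("+", fwd_codes, fwd_diags),
                                 ("-", rc_codes, rc_diags)):
        for gi, offset in sorted(diags):
            seg = best_segment_on_diagonal(codes, index.codes[gi], offset)
            if seg is None:
                continue
            score, matches, g_start, g_end, _, _ = seg
            length = g_end - g_start
            hits.append(RecruitmentHit(
                read_id=read_id,
                genome_id=index.ids[gi],
                g_start=g_start,
                g_end=g_end,
                strand=strand,
                identity=matches / length,
                read_cov=length / read_len,
                aligned_nt=length,
                score=score,
            ))
    return hits


def align_read_local(read_seq: str, genome: Genome, k: int = DEFAULT_SEED_K,
                     query_step: int = 1, index: SeedIndex | None = None
                     ) -> RecruitmentHit | None:
    """Best ungapped local placement of one read on one genome, or None.

    A genome shorter than the seed size simply yields no hit.
    """
    read_seq = read_seq.upper()
    if len(read_seq) < k:
        raise ValueError(f"read shorter than seed size k={k}")
    if index is None:
        if len(genome) < k:
            return None
        index = SeedIndex([genome], k=k)
    fwd = encode(read_seq)
    rc = revcomp_codes(fwd)
    fwd_diags = index.candidate_diagonals(read_seq, query_step)
    from .genomes import decode
    rc_diags = index.candidate_diagonals(decode(rc), query_step)
    hits = _evaluate_candidates("read", len(read_seq), fwd, rc, index,
                                fwd_diags, rc_diags)
    if not hits:
        return None
    return min(hits, key=_hit_sort_key)


def align_reads(reads_ids: list[str], reads_seqs: list[str], index: SeedIndex,
                min_read_cov: float = 0.0, min_identity: float = 0.0,
                query_step: int = 1, best_per_genome: bool = False,
                ) -> list[RecruitmentHit]:
    """Place many reads against an index; at most one hit per read (default)
    or one best hit per (read, genome) when ``best_per_genome`` is set.

    Filters are applied before best-hit selection, mirroring the coverage/
    identity cut-offs of the published recruitment step.
    """
    from .genomes import decode

    out: list[RecruitmentHit] = []
    for rid, seq in zip(reads_ids, reads_seqs):
        seq = seq.upper()
        if len(seq) < index.k:
            continue
        fwd = encode(seq)
        rc = revcomp_codes(fwd)
        fwd_diags = index.candidate_diagonals(seq, query_step)
        rc_diags = index.candidate_diagonals(decode(rc), query_step)
        if not fwd_diags and not rc_diags:
            continue
        hits = _evaluate_candidates(rid, len(seq), fwd, rc, index,
                                    fwd_diags, rc_diags)
        hits = [h for h in hits
                if h.read_cov >= min_read_cov and h.identity >= min_identity]
        if not hits:
            continue
        if best_per_genome:
            best: dict[str, RecruitmentHit] = {}
            for h in sorted(hits, key=_hit_sort_key):
                best.setdefault(h.genome_id, h)
            out.extend(best[g] for g in sorted(best))
        else:
            out.append(min(hits, key=_hit_sort_key))
    return out
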