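"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the package's own code paths: alignment is an
exhaustive scan over every diagonal of both strands, codon recounting uses a
hard-coded genetic code, and depth counting stabs every position.
"""

from __future__ import annotations

STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def dp_local_ungapped(read: str, genome: str):
    """Exhaustive ungapped local alignment over every diagonal and strand.

    Scoring: match +1, mismatch -1; the best segment per diagonal takes the
    smallest end then the smallest start among score ties; across segments
    the winner maximises (score, length), then prefers '+' over '-', then
    the smaller genome start. Returns (score, matches, g_start, g_end,
    strand) or None.
    """
    best = None
    for strand in "+-":
        seq = read if strand == "+" else rc(read)
        rl, gl = len(seq), len(genome)
        for offset in range(-(rl - 1), gl):
            a, b = max(0, offset), min(gl, offset + rl)
            if b <= a:
                continue
            # Kadane with explicit first-smallest-end / first-start ties
            seg_best = None
            run_start, run_score = 0, 0
            prefix_min, prefix_argmin = 0, 0
            csum = 0
            for idx in range(b - a):
                match = genome[a + idx] == seq[a - offset + idx]
                csum += 1 if match else -1
                score = csum - prefix_min
                if seg_best is None or score > seg_best[0]:
                    seg_best = (score, prefix_argmin, idx + 1)
                if csum < prefix_min:
                    prefix_min, prefix_argmin = csum, idx + 1
            if seg_best is None or seg_best[0] <= 0:
                continue
            score, s, e = seg_best
            length = e - s
            cand = (score, length, strand, a + s, a + e)
            if best is None:
                best = cand
            else:
                key_new = (-cand[0], -cand[1], cand[2], cand[3])
                key_old = (-best[0], -best[1], best[2], best[3])
                if key_new < key_old:
                    best = cand
    if best is None:
        return None
    score, length, strand, g_start, g_end = best
    matches = (length + score) // 2
    return score, matches, g_start, g_end, strand


def codon_recount(orf_seq: str, segments, min_aa_cov: int = 5,
                  min_mut_codon_count: int = 4,
                  min_mut_codon_freq: float = 1.0):
    """Per-codon recount: returns {codon_index: (coverage, ref, {alt: count},
    syn, nonsyn)} for codons with counted alternatives."""
    n_codons = len(orf_seq) // 3
    out = {}
    for ci in range(n_codons):
        lo, hi = 3 * ci, 3 * ci + 3
        observed = []
        for offset, seq in segments:
            if offset <= lo and offset + len(seq) >= hi:
                observed.append(seq[lo - offset:hi - offset])
        coverage = len(observed)
        if coverage < min_aa_cov:
            continue
        ref = orf_seq[lo:hi]
        alts, syn, nonsyn = {}, 0, 0
        for codon in sorted(set(observed)):
            count = observed.count(codon)
            if codon == ref or "N" in codon:
                continue
            if count < min_mut_codon_count:
                continue
            if 100.0 * count / coverage < min_mut_codon_freq:
                continue
            alts[codon] = count
            if STANDARD_CODE[codon] == STANDARD_CODE[ref]:
                syn += count
            else:
                nonsyn += count
        if alts:
            out[ci] = (coverage, ref, alts, syn, nonsyn)
    return out


def stab_depth(hits, length: int):
    """Per-position coverage by checking every (position, hit) pair."""
    return [sum(1 for h in hits if h.g_start <= pos < h.g_end)
            for pos in range(length)]


def orf_scan_6frame(seq: str, min_len: int = 300):
    """All maximal start-to-stop ORFs >= min_len, forward coordinates."""
    stops = {"TAA", "TAG", "TGA"}
    found = []
    length = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else rc(seq)
        for frame in range(3):
            start = None
            for pos in range(frame, length - 2, 3):
                codon = s[pos:pos + 3]
                if start is None:
                    if codon == "ATG":
                        start = pos
                elif codon in stops:
                    end = pos + 3
                    if end - start >= min_len:
                        if strand == "+":
                            found.append((start, end, "+"))
                        else:
                            found.append((length - end, length - start, "-"))
                    start = None
    return sorted(found)
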