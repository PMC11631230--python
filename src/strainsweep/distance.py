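"""Whole-read-set comparison by bottom-s MinHash sketching.

Canonical k-mers (the lexicographically smaller of a k-mer and its reverse
complement, compared on hash values) are filtered by multiplicity
(min_count, default 2, suppressing single-copy sequencing-error k-mers),
hashed with a fixed 64-bit mixer (splitmix64) and summarised by the s
smallest distinct hash values. Two sketches give a Jaccard estimate from
the bottom-s' of their merged union and the Mash distance
D = -(1/k) ln(2j / (1 + j)), capped at 1 when the sketches are disjoint.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .genomes import encode

_SPLITMIX_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)


def splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorised splitmix64 finaliser on uint64 arrays."""
    z = (x + _SPLITMIX_GAMMA).astype(np.uint64)
    z ^= z >> np.uint64(30)
    z *= _MIX1
    z ^= z >> np.uint64(27)
    z *= _MIX2
    z ^= z >> np.uint64(31)
    return z


@dataclass
class Sketch:
    k: int
    s: int
    min_count: int
    hashes: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.uint64))

    def __post_init__(self):
        self.hashes = np.asarray(self.hashes, dtype=np.uint64)
        if self.hashes.size > self.s:
            raise ValueError("sketch larger than its nominal size")

    def to_dict(self) -> dict:
        return {"k": self.k, "s": self.s, "min_count": self.min_count,
                "hashes": [int(h) for h in self.hashes]}

    @classmethod
    def from_dict(cls, d: dict) -> "Sketch":
        return cls(k=d["k"], s=d["s"], min_count=d["min_count"],
                   hashes=np.array(d["hashes"], dtype=np.uint64))


def canonical_kmer_codes(seqs: list[str], k: int) -> np.ndarray:
    """All canonical k-mers of a read set, 2-bit packed into uint64.

    K-mers touching an ambiguous base are dropped. Requires k <= 31.
    """
    if k > 31:
        raise ValueError("k must be <= 31 for 64-bit packing")
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    chunks: list[np.ndarray] = []
    for seq in seqs:
        codes = encode(seq.upper())
        if codes.size < k:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = ~(windows == 4).any(axis=1)
        if not valid.any():
            continue
        fwd64 = windows[valid].astype(np.uint64)
        fwd = fwd64 @ powers
        rc = (np.uint64(3) - fwd64)[:, ::-1] @ powers
        chunks.append(np.minimum(fwd, rc))
    if not chunks:
        return np.array([], dtype=np.uint64)
    return np.concatenate(chunks)


def minhash_sketch(reads, k: int = 21, s: int = 10000, min_count: int = 2) -> Sketch:
    """Bottom-s sketch of a read set's canonical k-mer content."""
    from .simulate import SampleReads

    seqs = reads.seqs if isinstance(reads, SampleReads) else list(reads)
    if not seqs:
        raise ValueError("empty read set")
    if any(len(seq) < k for seq in seqs) and all(len(seq) < k for seq in seqs):
        raise ValueError(f"all reads shorter than k={k}")
    kmers = canonical_kmer_codes(seqs, k)
    if kmers.size == 0:
        return Sketch(k=k, s=s, min_count=min_count)
    values, counts = np.unique(kmers, return_counts=True)
    kept = values[counts >= min_count]
    hashes = np.sort(splitmix64(kept))
    return Sketch(k=k, s=s, min_count=min_count, hashes=hashes[:s])


def mash_distance(sk1: Sketch, sk2: Sketch) -> float:
    """Mash distance from two sketches; disjoint sketches give 1."""
    if sk1.k != sk2.k:
        raise ValueError(f"mismatched k: {sk1.k} vs {sk2.k}")
    if sk1.hashes.size == 0 or sk2.hashes.size == 0:
        return 1.0
    union = np.union1d(sk1.hashes, sk2.hashes)
    s_prime = min(min(sk1.s, sk2.s), union.size)
    merged = union[:s_prime]
    shared = np.intersect1d(merged, sk1.hashes, assume_unique=True)
    shared = np.intersect1d(shared, sk2.hashes, assume_unique=True)
    j = shared.size / s_prime
    if j == 0:
        return 1.0
    d = -np.log(2.0 * j / (1.0 + j)) / sk1.k
    return float(min(max(d, 0.0), 1.0))


def exact_jaccard_distance(seqs_a: list[str], seqs_b: list[str], k: int = 21,
                           min_count: int = 2) -> float:
    """Mash-formula distance from exact (unsketched) k-mer sets — the
    oracle counterpart of the sketch estimate."""
    def kept_set(seqs):
        kmers = canonical_kmer_codes(seqs, k)
        if kmers.size == 0:
            return np.array([], dtype=np.uint64)
        values, counts = np.unique(kmers, return_counts=True)
        return values[counts >= min_count]

    a, b = kept_set(seqs_a), kept_set(seqs_b)
    if a.size == 0 or b.size == 0:
        return 1.0
    inter = np.intersect1d(a, b, assume_unique=True).size
    j = inter / (a.size + b.size - inter)
    if j == 0:
        return 1.0
    return float(min(max(-np.log(2.0 * j / (1.0 + j)) / k, 0.0), 1.0))


def distance_matrix(sketches: dict[str, Sketch]):
    import pandas as pd

    ids = sorted(sketches)
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            d = mash_distance(sketches[a], sketches[b])
            mat.loc[a, b] = d
            mat.loc[b, a] = d
    return mat


def write_sketches(sketches: dict[str, Sketch], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump({name: sk.to_dict() for name, sk in sorted(sketches.items())},
                  fh, sort_keys=True)


def read_sketches(path: str | os.PathLike) -> dict[str, Sketch]:
    with open(path) as fh:
        payload = json.load(fh)
    return {name: Sketch.from_dict(d) for name, d in payload.items()}
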