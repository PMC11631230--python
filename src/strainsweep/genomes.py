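"""Genome container and sequence/interval I/O.

Sequences are plain uppercase strings over {A,C,G,T,N}; hot paths work on
numpy uint8 code arrays (A=0, C=1, G=2, T=3, N=4). Coordinates are 0-based,
half-open everywhere; on disk ORFs are BED6.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_ALPHABET = "ACGTN"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Map a sequence string to uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement on code arrays; N (4) stays N."""
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def gc_fraction(seq: str) -> float:
    codes = encode(seq)
    return float(np.mean((codes == 1) | (codes == 2)))


@dataclass
class Genome:
    """A reference genome with optional ORF annotation and truth labels.

    orfs are (start, end, strand) tuples, 0-based half-open on the forward
    coordinate system; coding length (end - start) must be divisible by 3.
    """

    id: str
    sequence: str
    orfs: list[tuple[int, int, str]] = field(default_factory=list)
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"genome {self.id}: empty sequence")
        self.sequence = self.sequence.upper()
        for start, end, strand in self.orfs:
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(
                    f"genome {self.id}: ORF ({start},{end}) out of bounds"
                )
            if (end - start) % 3:
                raise ValueError(
                    f"genome {self.id}: ORF ({start},{end}) length not divisible by 3"
                )
            if strand not in "+-":
                raise ValueError(f"genome {self.id}: bad strand {strand!r}")
        self._codes: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        if self._codes is None:
            self._codes = encode(self.sequence)
        return self._codes

    def n_ambiguous(self) -> int:
        return int(np.sum(self.codes == 4))


def write_fasta(genomes: list[Genome], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> list[Genome]:
    return [
        Genome(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_orfs_bed(genomes: list[Genome], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            for i, (start, end, strand) in enumerate(g.orfs):
                fh.write(
                    f"{g.id}\t{start}\t{end}\t{g.id}_orf{i + 1:03d}\t0\t{strand}\n"
                )


def read_orfs_bed(path: str | os.PathLike) -> dict[str, list[tuple[int, int, str]]]:
    out: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) > 5 else "+"
            out.setdefault(chrom, []).append((start, end, strand))
    return out


def attach_orfs(genomes: list[Genome], orfs: dict[str, list[tuple[int, int, str]]]) -> None:
    for g in genomes:
        if g.id in orfs:
            g.orfs = list(orfs[g.id])
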