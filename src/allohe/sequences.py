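"""Nucleotide sequence containers and 2-bit encoding helpers.

Genomes are held in memory as ``uint8`` code arrays (A=0, C=1, G=2, T=3),
which keeps exact k-mer hashing, substitution simulation and window
arithmetic vectorisable with numpy. FASTA I/O goes through Biopython.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# ASCII -> 2-bit code lookup; 255 marks anything that is not A/C/G/T.
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[ord(chr(_b).lower())] = _i


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a DNA string into a uint8 code array (A=0, C=1, G=2, T=3)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    codes = _ENCODE[np.frombuffer(seq, dtype=np.uint8)]
    if (codes == 255).any():
        bad = bytes(np.frombuffer(seq, dtype=np.uint8)[codes == 255][:5])
        raise ValueError(f"non-ACGT symbols in sequence: {bad!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back into a DNA string."""
    return _BASES[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array (complement of code c is 3-c)."""
    return (3 - codes)[::-1]


@dataclass
class Genome:
    """An in-memory genome: ordered chromosomes of 2-bit encoded sequence.

    ``subgenome`` maps chromosome name to a subgenome label ("a" / "f") for
    hybrid genomes; ancestral genomes leave it empty (label "none").
    """

    genome_id: str
    names: list[str]
    seqs: dict[str, np.ndarray]
    subgenome: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        for name in self.names:
            if name not in self.seqs:
                raise ValueError(f"missing sequence for chromosome {name}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.seqs[name]

    def length(self, name: str) -> int:
        return int(self.seqs[name].size)

    @property
    def lengths(self) -> dict[str, int]:
        return {n: int(self.seqs[n].size) for n in self.names}

    def label(self, name: str) -> str:
        return self.subgenome.get(name, "none")

    def layout(self):
        from .layout import Chromosome, GenomeLayout

        return GenomeLayout(
            self.genome_id,
            tuple(
                Chromosome(n, self.length(n), self.label(n)) for n in self.names
            ),
        )

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        genome_id: str | None = None,
        subgenome: dict[str, str] | None = None,
    ) -> "Genome":
        names: list[str] = []
        seqs: dict[str, np.ndarray] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            seqs[rec.id] = encode(str(rec.seq))
        if not names:
            raise ValueError(f"no sequences in {path}")
        return cls(genome_id or Path(path).stem, names, seqs, subgenome or {})

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        records = (
            SeqRecord(Seq(decode(self.seqs[n])), id=n, description="")
            for n in self.names
        )
        with open(path, "w") as handle:
            SeqIO.write(records, handle, "fasta")


@dataclass
class PairedReads:
    """Error-free paired-end reads as dense code matrices.

    ``r1``/``r2`` are (n_pairs, read_length) uint8 arrays. Ground-truth
    sampling coordinates are carried alongside so simulations can be checked
    read-by-read; they are ignored by the mapper.
    """

    r1: np.ndarray
    r2: np.ndarray
    truth_chrom: np.ndarray | None = None  # chromosome index per pair
    truth_start1: np.ndarray | None = None  # leftmost base of forward mate
    truth_start2: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.r1.shape != self.r2.shape:
            raise ValueError("mate matrices must have identical shape")

    @property
    def n_pairs(self) -> int:
        return int(self.r1.shape[0])

    @property
    def read_length(self) -> int:
        return int(self.r1.shape[1])

    def subset(self, mask: np.ndarray) -> "PairedReads":
        take = lambda a: None if a is None else a[mask]
        return PairedReads(
            self.r1[mask], self.r2[mask],
            take(self.truth_chrom), take(self.truth_start1), take(self.truth_start2),
        )

    def to_fastq(self, path1: str | Path, path2: str | Path, prefix: str = "frag") -> None:
        qual = "I" * self.read_length
        for path, mat, mate in ((path1, self.r1, 1), (path2, self.r2, 2)):
            with open(path, "w") as fh:
                for i in range(self.n_pairs):
                    fh.write(f"@{prefix}{i}/{mate}\n{decode(mat[i])}\n+\n{qual}\n")

    @classmethod
    def from_fastq(cls, path1: str | Path, path2: str | Path) -> "PairedReads":
        def load(path):
            rows = []
            for j, rec in enumerate(_iter_fastq(path)):
                rows.append(encode(rec))
            if not rows:
                raise ValueError(f"no reads in {path}")
            return np.vstack(rows)

        return cls(load(path1), load(path2))


def _iter_fastq(path: str | Path):
    with open(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual or not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"truncated or malformed FASTQ record {idx} in {path}")
            idx += 1
            yield seq.strip()
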