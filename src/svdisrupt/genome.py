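"""Genome sequence accessors: FASTA-backed and in-memory."""

from __future__ import annotations

from typing import Mapping, Protocol

from pyfaidx import Fasta


class GenomeSource(Protocol):
    """Anything that can hand out uppercase reference sequence."""

    def fetch(self, chrom: str, start: int, end: int) -> str: ...

    def chrom_length(self, chrom: str) -> int: ...

    def chromosomes(self) -> list[str]: ...


class DictGenome:
    """In-memory genome, the workhorse for synthetic fixtures and tests."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {c: s.upper() for c, s in sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq):
            raise ValueError(
                f"fetch {chrom}:{start}-{end} outside contig of length {len(seq)}"
            )
        return seq[start:end]

    def chrom_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def chromosomes(self) -> list[str]:
        return list(self._seqs)


class FastaGenome:
    """Random-access FASTA genome via an on-disk index."""

    def __init__(self, path: str):
        self._fasta = Fasta(path, sequence_always_upper=True)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if start < 0 or end > self.chrom_length(chrom):
            raise ValueError(f"fetch {chrom}:{start}-{end} outside contig")
        return str(self._fasta[chrom][start:end])

    def chrom_length(self, chrom: str) -> int:
        return len(self._fasta[chrom])

    def chromosomes(self) -> list[str]:
        return list(self._fasta.keys())
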