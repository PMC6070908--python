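"""Core record types shared across the pipeline.

Coordinates are 1-based inclusive throughout (GFF3 convention). Genome
sequences are uppercase DNA over {A, C, G, T, N}; assemblies of cohesive-end
phages are circular permutations of the packaged molecule, so most records
carry ``topology="circular_permuted"``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeRecord:
    """One phage contig."""

    id: str
    seq: str
    topology: str = "circular_permuted"  # or "linear"
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if len(self.seq) < 1:
            raise ValueError(f"genome {self.id!r} is empty")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(f"genome {self.id!r} has non-DNA characters: {sorted(bad)}")
        if self.topology not in ("circular_permuted", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.seq)

    def slice_circular(self, start: int, length: int) -> str:
        """Substring of `length` bases beginning at 1-based `start`, wrapping."""
        L = len(self.seq)
        i = (start - 1) % L
        doubled = self.seq + self.seq
        return doubled[i : i + length]

    def rotated(self, offset: int, new_id: str | None = None) -> "GenomeRecord":
        """Rotation moving base ``offset+1`` to base 1 (offset in [0, L))."""
        L = len(self.seq)
        r = offset % L
        return GenomeRecord(
            id=new_id or self.id,
            seq=self.seq[r:] + self.seq[:r],
            topology=self.topology,
            notes=dict(self.notes),
        )


@dataclass
class PackagingCall:
    """Detected (or ground-truth) DNA-packaging strategy for one genome.

    For cos strategies, ``overhang_seq`` is the observed overhang and
    ``junction`` the 1-based position of the first base after the cos site
    in the orientation of the genome the call refers to.  For DTR,
    ``junction`` is the first base of the repeat.
    """

    strategy: str = "unknown"  # cos3 | cos5 | dtr | unknown
    overhang_seq: str = ""
    overhang_len: int = 0
    dtr_len: int = 0
    junction: int = 0
    mismatches: int = 0
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strategy not in ("cos3", "cos5", "dtr", "unknown"):
            raise ValueError(f"unknown packaging strategy {self.strategy!r}")
        if self.strategy in ("cos3", "cos5"):
            if self.overhang_len != len(self.overhang_seq) or self.overhang_len == 0:
                raise ValueError("cos call requires a non-empty overhang")
            if self.dtr_len != 0:
                raise ValueError("cos call cannot carry a DTR length")
        elif self.strategy == "dtr":
            if self.dtr_len <= 0 or self.overhang_len != 0 or self.overhang_seq:
                raise ValueError("dtr call requires dtr_len > 0 and no overhang")
        else:
            if self.overhang_seq or self.overhang_len or self.dtr_len:
                raise ValueError("unknown call must be all zero/empty")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PackagingCall":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def read_fasta(path) -> list[GenomeRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(GenomeRecord(id=rec.id, seq=str(rec.seq)))
    return out


def write_fasta(records: Iterable[GenomeRecord], path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.notes.get("description", ""))
        for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def write_fastq(reads: Iterable[tuple[str, str]], path) -> None:
    """Write (name, sequence) pairs as FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> Iterator[tuple[str, str]]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq)
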