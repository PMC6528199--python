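"""Reference genome and 3' interval handling.

Sequences are held as numpy uint8 code arrays (A=0, C=1, G=2, T=3, N=4),
the representation every downstream stage (seeding, alignment, pileup)
operates on.  Intervals follow BED conventions: 0-based, half-open,
stranded.  For a minus-strand interval the transcript sequence is the
reverse complement of the genome slice, and the "3' end" of the transcript
is the interval's *left* genomic edge.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

A, C, G, T, N = 0, 1, 2, 3, 4
BASES = "ACGTN"

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

# complement in code space; N stays N
_COMPLEMENT = np.array([T, G, C, A, N], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into a uint8 code array."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back into a string."""
    return "".join(BASES[c] for c in codes)


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space."""
    return _COMPLEMENT[codes[::-1]]


@dataclass(frozen=True)
class Interval:
    """A stranded 3' interval (BED6 record)."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    name: str
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"malformed interval {self.name}: start {self.start} >= end {self.end}"
            )
        if self.strand not in "+-":
            raise ValueError(f"interval {self.name}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


class ReferenceBundle:
    """Genome sequences plus the stranded 3' interval annotation.

    The coordinate frame for everything downstream: alignment positions,
    SNP masks and per-T-position counters all refer to these chromosomes.
    """

    def __init__(self, sequences: dict[str, np.ndarray], intervals: list[Interval]):
        self.sequences = sequences
        self.intervals = list(intervals)
        for iv in self.intervals:
            if iv.chrom not in sequences:
                raise KeyError(f"interval {iv.name} references unknown contig {iv.chrom}")
            if iv.end > len(sequences[iv.chrom]):
                raise ValueError(f"interval {iv.name} extends past end of {iv.chrom}")
        self._by_name = {iv.name: iv for iv in self.intervals}

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        nbp = sum(len(s) for s in self.sequences.values())
        return (
            f"ReferenceBundle({len(self.sequences)} contigs, {nbp} bp, "
            f"{len(self.intervals)} intervals)"
        )

    def interval(self, name: str) -> Interval:
        return self._by_name[name]

    def interval_sequence(self, iv: Interval | str) -> np.ndarray:
        """Transcript-strand sequence of an interval (reverse complemented
        for minus-strand intervals)."""
        if isinstance(iv, str):
            iv = self._by_name[iv]
        s = self.sequences[iv.chrom][iv.start : iv.end]
        return revcomp(s) if iv.strand == "-" else s

    def terminal_window(self, iv: Interval | str, length: int = 250) -> tuple[int, int]:
        """Genomic (start, end) of the last `length` bp of the transcript,
        i.e. the 3'-most window that 3' end sequencing actually covers."""
        if isinstance(iv, str):
            iv = self._by_name[iv]
        w = min(length, iv.length)
        if iv.strand == "+":
            return iv.end - w, iv.end
        return iv.start, iv.start + w

    # ------------------------------------------------------------------ io

    @classmethod
    def from_files(cls, fasta: str | Path, bed: str | Path) -> "ReferenceBundle":
        return cls(read_fasta(fasta), read_bed(bed))

    def write(self, fasta: str | Path, bed: str | Path) -> None:
        write_fasta(fasta, self.sequences)
        write_bed(bed, self.intervals)


# ---------------------------------------------------------------------- FASTA


def read_fasta(path: str | Path) -> dict[str, np.ndarray]:
    return {rec.id: encode(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: dict[str, np.ndarray]) -> None:
    records = [
        SeqRecord(Seq(decode(codes)), id=name, description="")
        for name, codes in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ------------------------------------------------------------------------ BED


def read_bed(path: str | Path) -> list[Interval]:
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 requires 6 columns")
            try:
                iv = Interval(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=fields[3],
                    strand=fields[5],
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            intervals.append(iv)
    return intervals


def write_bed(path: str | Path, intervals: Iterable[Interval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def intervals_to_frame(intervals: Iterable[Interval]) -> pd.DataFrame:
    return pd.DataFrame(
        [(iv.chrom, iv.start, iv.end, iv.name, iv.strand) for iv in intervals],
        columns=["chrom", "start", "end", "name", "strand"],
    )
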