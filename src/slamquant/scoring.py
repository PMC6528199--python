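"""Conversion-aware alignment scoring.

The asymmetric substitution scheme at the core of the mapper: matches score
+10, mismatches -15, except the labeling-diagnostic reference-T -> read-C
mismatch, which scores 0 (neither rewarded nor penalized).  Direction
matters: read-T against reference-C is an ordinary -15 mismatch.

Conversions are defined on the transcribed strand, so for an alignment on
the genomic minus strand the free mismatch becomes reference-A / read-G in
genome-forward coordinates (the read being held reverse-complemented).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import A, C, G, T, N, encode


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution and gap scores for conversion-aware local alignment.

    With conversion_aware off the T>C cell reverts to the ordinary mismatch
    penalty, giving the standard scoring an RNA-seq mapper would use.
    Gap penalties are chosen so that any gap costs more than any mismatch.
    """

    match_score: int = 10
    mismatch_score: int = -15
    tc_score: int = 0
    gap_open: int = -20
    gap_extend: int = -5
    conversion_aware: bool = True

    def __post_init__(self) -> None:
        if not self.match_score > 0 > self.mismatch_score:
            raise ValueError("need match_score > 0 > mismatch_score")
        if self.effective_tc_score < self.mismatch_score:
            raise ValueError("tc_score must be >= mismatch_score")

    @property
    def effective_tc_score(self) -> int:
        return self.tc_score if self.conversion_aware else self.mismatch_score

    def matrix(self, strand: str = "+") -> np.ndarray:
        """5x5 substitution matrix indexed [ref_code, read_code].

        strand '+' puts the free pass at (T, C); strand '-' at (A, G),
        i.e. transcript-space T>C seen through a reverse-complemented read.
        N scores 0 against anything.
        """
        m = np.full((5, 5), self.mismatch_score, dtype=np.int32)
        np.fill_diagonal(m, self.match_score)
        m[N, :] = 0
        m[:, N] = 0
        if strand == "+":
            m[T, C] = self.effective_tc_score
        else:
            m[A, G] = self.effective_tc_score
        return m


def conversion_pair(strand: str) -> tuple[int, int]:
    """(ref, read) code pair that constitutes a T>C conversion in
    genome-forward coordinates for an alignment on `strand`."""
    return (T, C) if strand == "+" else (A, G)


def score_pair(ref_base: str | int, read_base: str | int, scheme: ScoringScheme,
               strand: str = "+") -> int:
    """Score a single aligned column under the scheme."""
    r = ref_base if isinstance(ref_base, (int, np.integer)) else int(encode(ref_base)[0])
    q = read_base if isinstance(read_base, (int, np.integer)) else int(encode(read_base)[0])
    return int(scheme.matrix(strand)[r, q])
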