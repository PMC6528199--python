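"""Alignment filtering and multimapper assignment to 3' intervals.

Alignments are kept when they reach 95% sequence identity (T>C conversion
columns count as matches — the conversion is the signal the protocol
creates, not an error; configurable) over at least 50% of the read bases.

A read's kept locations are then reconciled against the de-overlapped 3'
interval annotation:

* no location overlaps any interval      -> discarded (outside_intervals)
* locations in exactly one interval      -> assigned to it; if several
  locations fall in that interval, one is picked at random (seeded)
* one interval plus non-interval copies  -> assigned to the interval
  (the non-interval copies are decoys, e.g. a pseudogene or intron)
* locations in two or more intervals     -> discarded (ambiguous)

With multimapper recovery off any read with more than one kept location is
discarded instead.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import Alignment, ReadMapping
from .genome import Interval

DROP_LOW_QUALITY = "low_quality"
DROP_OUTSIDE = "outside_intervals"
DROP_AMBIGUOUS = "ambiguous_multi_interval"
DROP_TOO_MANY = "too_many_locations"
DROP_UNMAPPED = "unmapped"
DROP_MULTIMAPPER = "multimapper_recovery_off"


@dataclass
class FilterConfig:
    min_identity: float = 0.95
    min_aligned_fraction: float = 0.5
    multimapper_recovery: bool = True
    conversions_count_as_matches: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.min_identity, self.min_aligned_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("filter fractions must be in [0, 1]")


def filter_alignment(a: Alignment, cfg: FilterConfig) -> bool:
    """True if the alignment passes the identity / aligned-fraction gates."""
    ident = a.identity if cfg.conversions_count_as_matches else a.identity_strict
    return ident >= cfg.min_identity and a.aligned_fraction >= cfg.min_aligned_fraction


class IntervalIndex:
    """Strand-aware point/range overlap queries against de-overlapped
    intervals (sorted starts + bisect; intervals must not overlap within a
    chrom/strand)."""

    def __init__(self, intervals: Sequence[Interval]):
        self.intervals = list(intervals)
        self._by_key: dict[tuple[str, str], tuple[list[int], list[int], list[int]]] = {}
        tmp: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
        for i, iv in enumerate(self.intervals):
            tmp.setdefault((iv.chrom, iv.strand), []).append((iv.start, iv.end, i))
        for key, rows in tmp.items():
            rows.sort()
            starts = [r[0] for r in rows]
            ends = [r[1] for r in rows]
            idx = [r[2] for r in rows]
            for a, b in zip(ends, starts[1:]):
                if b < a:
                    raise ValueError("IntervalIndex requires de-overlapped intervals")
            self._by_key[key] = (starts, ends, idx)

    def overlapping(self, chrom: str, start: int, end: int, strand: str) -> Interval | None:
        """The interval overlapping [start, end) on the given strand by
        >= 1 bp, or None."""
        entry = self._by_key.get((chrom, strand))
        if entry is None:
            return None
        starts, ends, idx = entry
        i = bisect_right(starts, end - 1) - 1
        if i >= 0 and ends[i] > start:
            return self.intervals[idx[i]]
        return None


@dataclass
class AssignedRead:
    name: str
    interval: str
    alignment: Alignment


@dataclass
class AssignmentResult:
    assigned: list[AssignedRead]
    drop_reasons: Counter = field(default_factory=Counter)

    def summary(self) -> pd.DataFrame:
        rows = [("assigned", len(self.assigned))]
        rows += sorted(self.drop_reasons.items())
        return pd.DataFrame(rows, columns=["outcome", "n_reads"])


def assign_read(
    kept: Sequence[Alignment],
    index: IntervalIndex,
    rng: np.random.Generator,
    multimapper_recovery: bool = True,
) -> tuple[str | None, Alignment | None, str | None]:
    """Assign one read's kept alignments to a 3' interval.

    Returns (interval_name, chosen_alignment, drop_reason); exactly one of
    interval_name / drop_reason is set.
    """
    if not kept:
        return None, None, DROP_LOW_QUALITY
    if not multimapper_recovery and len(kept) > 1:
        return None, None, DROP_MULTIMAPPER
    hits: list[tuple[str, Alignment]] = []
    names: set[str] = set()
    for a in kept:
        iv = index.overlapping(a.chrom, a.pos, a.end, a.strand)
        if iv is not None:
            hits.append((iv.name, a))
            names.add(iv.name)
    if not names:
        return None, None, DROP_OUTSIDE
    if len(names) > 1:
        return None, None, DROP_AMBIGUOUS
    name = names.pop()
    in_iv = [a for n, a in hits if n == name]
    chosen = in_iv[int(rng.integers(len(in_iv)))] if len(in_iv) > 1 else in_iv[0]
    return name, chosen, None


def filter_and_assign(
    mappings: Iterable[ReadMapping],
    intervals: Sequence[Interval],
    cfg: FilterConfig | None = None,
) -> AssignmentResult:
    """Apply quality filters and interval assignment to a whole read set.

    Reads are processed in input order with a single seeded generator, so
    multimapper tie-breaking is reproducible.
    """
    cfg = cfg or FilterConfig()
    rng = np.random.default_rng(cfg.seed)
    index = IntervalIndex(intervals)
    result = AssignmentResult(assigned=[])
    for m in mappings:
        if m.status == "unmapped":
            result.drop_reasons[DROP_UNMAPPED] += 1
            continue
        if m.status == "discarded_too_many_locations":
            result.drop_reasons[DROP_TOO_MANY] += 1
            continue
        kept = [a for a in m.alignments if filter_alignment(a, cfg)]
        name, chosen, reason = assign_read(kept, index, rng, cfg.multimapper_recovery)
        if reason is not None:
            result.drop_reasons[reason] += 1
        else:
            result.assigned.append(AssignedRead(m.name, name, chosen))
    return result


def counts_per_interval(result: AssignmentResult, intervals: Sequence[Interval]) -> pd.Series:
    counts = Counter(r.interval for r in result.assigned)
    return pd.Series(
        {iv.name: counts.get(iv.name, 0) for iv in intervals}, name="n_reads", dtype=int
    )
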