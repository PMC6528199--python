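"""Sample-level QC profiles and k-mer mappability assessment.

Mismatch profiles break per-cycle error rates down by substitution type so
that bad sequencing cycles (spikes in non-T>C mismatch rates) and the
labeling signal (elevated T>C rate) are immediately visible, with and
without base-quality filtering.  The positional conversion profile
aggregates T>C rates over a static 250 bp window at 3' ends in transcript
orientation.

Mappability is exact k-mer uniqueness: each position scores 1/multiplicity
of its k-mer, counted over both genome strands (the aligner maps both
strands, so a reverse-complement copy makes a position just as ambiguous
as a forward copy).  Interval %-uniqueness is the percentage of a
3' interval's k-mer start positions scoring exactly 1, binned in 5% steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import ReadMapping
from .filtering import AssignedRead
from .genome import BASES, Interval, ReferenceBundle, revcomp
from .variants import SnpMask, is_conversion

SUBSTITUTION_TYPES = [
    f"{r}>{q}" for r in "ACGT" for q in "ACGT" if r != q
]  # 12 (ref, read) pairs


@dataclass
class MismatchProfile:
    """Per-cycle mismatch rates by substitution type (12 x read_length)."""

    rates: pd.DataFrame  # index: substitution type, columns: read position
    counts: pd.DataFrame
    coverage: np.ndarray  # aligned reads covering each cycle
    min_base_quality: int = 0

    def overall_rates(self) -> pd.Series:
        total = self.coverage.sum()
        return self.counts.sum(axis=1) / max(total, 1)


def _iter_alignments(source: Iterable) -> Iterable:
    for item in source:
        if isinstance(item, AssignedRead):
            yield item.alignment
        elif isinstance(item, ReadMapping):
            if item.best is not None:
                yield item.best
        else:
            yield item


def mismatch_profiles(
    source: Iterable,
    read_length: int,
    mask: SnpMask | None = None,
    min_base_quality: int = 27,
) -> tuple[MismatchProfile, MismatchProfile]:
    """(unfiltered, base-quality-filtered) per-cycle mismatch profiles.

    Masked genomic positions are excluded from both profiles; the filtered
    profile additionally ignores mismatch bases below min_base_quality.
    T>C appears as its own substitution type, separate from the 11 others.
    """
    mask = mask or SnpMask()
    shape = (len(SUBSTITUTION_TYPES), read_length)
    raw = np.zeros(shape, dtype=np.int64)
    filt = np.zeros(shape, dtype=np.int64)
    coverage = np.zeros(read_length, dtype=np.int64)
    type_index = {t: i for i, t in enumerate(SUBSTITUTION_TYPES)}
    chrom_of = {}
    for a in _iter_alignments(source):
        coverage[: min(a.aligned_len, read_length)] += 1
        for mm in a.mismatches:
            if mm.ref >= 4 or mm.read >= 4:
                continue
            if (a.chrom, mm.gpos) in mask.snps:
                continue
            # report in transcript orientation so T>C means labeling signal
            if a.strand == "+":
                key = f"{BASES[mm.ref]}>{BASES[mm.read]}"
            else:
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                key = f"{comp[BASES[mm.ref]]}>{comp[BASES[mm.read]]}"
            i = type_index[key]
            if mm.read_pos < read_length:
                raw[i, mm.read_pos] += 1
                if mm.qual >= min_base_quality:
                    filt[i, mm.read_pos] += 1
    cov_safe = np.maximum(coverage, 1)
    mk = lambda counts, bq: MismatchProfile(
        rates=pd.DataFrame(counts / cov_safe, index=SUBSTITUTION_TYPES),
        counts=pd.DataFrame(counts, index=SUBSTITUTION_TYPES),
        coverage=coverage,
        min_base_quality=bq,
    )
    return mk(raw, 0), mk(filt, min_base_quality)


def conversion_rate_summary(
    samples: dict[str, Sequence[AssignedRead]],
    reference: ReferenceBundle,
    read_length: int,
    mask: SnpMask | None = None,
    min_base_quality: int = 27,
    conversion_threshold: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample substitution rates plus the intervals x samples T>C
    read-count matrix (the input for downstream ordination/PCA)."""
    from .quantify import count_conversions

    rate_rows = {}
    matrix = pd.DataFrame(
        0, index=[iv.name for iv in reference.intervals], columns=list(samples)
    )
    for name, assigned in samples.items():
        _, filt = mismatch_profiles(assigned, read_length, mask, min_base_quality)
        rate_rows[name] = filt.overall_rates()
        quants = count_conversions(
            assigned, reference, mask, min_base_quality, conversion_threshold
        )
        matrix[name] = pd.Series({q.interval: q.r_tc for q in quants.values()})
    rates = pd.DataFrame(rate_rows).T
    rates.index.name = "sample"
    return rates, matrix.fillna(0).astype(int)


def positional_conversion_profile(
    assigned: Sequence[AssignedRead],
    reference: ReferenceBundle,
    mask: SnpMask | None = None,
    min_base_quality: int = 27,
    window: int = 250,
) -> pd.DataFrame:
    """Per-position T>C rate over the terminal `window` bp of 3' intervals,
    in transcript orientation (position 0 = window start, window-1 = 3' end).

    Rate = converted T observations / T-position coverage at that offset;
    offsets with zero T coverage are NaN (undefined).
    """
    from .quantify import count_conversions

    conv = np.zeros(window, dtype=np.int64)
    cov = np.zeros(window, dtype=np.int64)
    quants = count_conversions(assigned, reference, mask, min_base_quality)
    for iv in reference.intervals:
        q = quants.get(iv.name)
        if q is None or q.t_count == 0:
            continue
        ws, we = reference.terminal_window(iv, window)
        wlen = we - ws
        # transcript-space offset of each T position (0 .. wlen-1)
        if iv.strand == "+":
            off = q.t_positions - ws
        else:
            off = we - 1 - q.t_positions
        # short intervals contribute only their 3'-most suffix
        off = off + (window - wlen)
        ok = (off >= 0) & (off < window)
        np.add.at(conv, off[ok], q.k[ok])
        np.add.at(cov, off[ok], q.c[ok])
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(cov > 0, conv / np.maximum(cov, 1), np.nan)
    return pd.DataFrame(
        {"position": np.arange(window), "conversions": conv, "t_coverage": cov,
         "rate": rate}
    )


# --------------------------------------------------------------- mappability


@dataclass
class MappabilityTrack:
    """Per-position 1/multiplicity scores for k-mer starts, per contig."""

    k: int
    scores: dict[str, np.ndarray]

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, s in self.scores.items():
                for i, v in enumerate(s):
                    fh.write(f"{chrom}\t{i}\t{i + 1}\t{v:.6g}\n")


def mappability_track(reference: ReferenceBundle | dict, k: int) -> MappabilityTrack:
    """Exact-match k-mer mappability: score(pos) = 1 / (occurrences of the
    k-mer starting at pos, counted over the genome and its reverse
    complement)."""
    sequences = (
        reference.sequences if isinstance(reference, ReferenceBundle) else reference
    )
    windows = []
    fwd_views = {}
    for name, seq in sequences.items():
        if len(seq) < k:
            fwd_views[name] = np.empty((0, k), dtype=np.uint8)
            continue
        sw = np.lib.stride_tricks.sliding_window_view(seq, k)
        fwd_views[name] = sw
        windows.append(sw)
        windows.append(np.lib.stride_tricks.sliding_window_view(revcomp(seq), k))
    if not windows:
        return MappabilityTrack(k, {n: np.empty(0) for n in sequences})
    allw = np.ascontiguousarray(np.concatenate(windows))
    flat = allw.view([("", allw.dtype)] * k).ravel()
    uniq, counts = np.unique(flat, return_counts=True)
    scores = {}
    for name, sw in fwd_views.items():
        if sw.shape[0] == 0:
            scores[name] = np.empty(0)
            continue
        q = np.ascontiguousarray(sw).view([("", sw.dtype)] * k).ravel()
        idx = np.searchsorted(uniq, q)
        scores[name] = 1.0 / counts[idx]
    return MappabilityTrack(k, scores)


def interval_uniqueness(
    track: MappabilityTrack, intervals: Sequence[Interval]
) -> pd.DataFrame:
    """%-uniqueness per interval (percentage of its k-mer start positions
    with score exactly 1) plus the 5% bin it falls in ([0,5) ... [95,100])."""
    edges = np.arange(0, 105, 5)
    rows = []
    for iv in intervals:
        s = track.scores.get(iv.chrom)
        hi = iv.end - track.k + 1
        if s is None or hi <= iv.start:
            rows.append((iv.name, np.nan, None, False))
            continue
        block = s[iv.start : hi]
        pct = 100.0 * float((block == 1.0).mean())
        b = min(int(pct // 5), 19)
        rows.append((iv.name, pct, f"[{edges[b]},{edges[b + 1]})", True))
    return pd.DataFrame(
        rows, columns=["interval", "pct_unique", "bin", "defined"]
    ).set_index("interval")
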