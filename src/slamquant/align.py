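"""Conversion-aware seed-and-extend read mapping.

The mapper indexes 13-mer seed words of the reference and looks them up
with conversion tolerance: a read seed hits an indexed k-mer if the two are
equal or differ only at positions where the reference has a T and the read
a C (transcript orientation; A/G on the genomic minus strand).  This is
implemented with a collapsed-alphabet index (T and C share a symbol for the
plus strand, A and G for the minus strand) followed by exact verification
of mismatch direction, so seeding is a handful of vectorized lookups per
read.

Seed hits sharing a diagonal are clustered into candidate mapping regions
(CMRs).  Each CMR is aligned with the conversion-aware scoring scheme:
a gapless scored extension along the dominant diagonal with local (score-
maximizing, longest-on-ties) trimming covers the ungapped case exactly,
and a full affine-gap Smith-Waterman over the CMR window takes over
whenever the gapless alignment looks poor.  Up to 100 locations are
reported per read; reads exceeding that are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .genome import A, C, G, T, N, BASES, Interval, ReferenceBundle, revcomp
from .scoring import ScoringScheme, conversion_pair

DEFAULT_K = 13

_POW4 = 4 ** np.arange(DEFAULT_K - 1, -1, -1, dtype=np.int64)
_COLLAPSE_TC = np.array([0, 1, 2, 1, 0], dtype=np.uint8)  # T -> C
_COLLAPSE_AG = np.array([0, 1, 0, 3, 0], dtype=np.uint8)  # G -> A


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 integer codes of all k-mers plus a validity mask (no N)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    clipped = np.where(codes < 4, codes, 0).astype(np.int64)
    pow4 = _POW4 if k == DEFAULT_K else 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    for j in range(k):
        out += clipped[j : j + n] * int(pow4[j])
    is_n = np.concatenate(([0], np.cumsum(codes == N)))
    valid = (is_n[k:] - is_n[:-k]) == 0
    return out, valid


class _SortedLookup:
    """Sorted (code -> positions) multimap queried with searchsorted."""

    def __init__(self, codes: np.ndarray, positions: np.ndarray):
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.positions = positions[order]

    def ranges(self, queries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self.codes, queries, side="left")
        hi = np.searchsorted(self.codes, queries, side="right")
        return lo, hi


def _multirange(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand [lo_i, hi_i) ranges into flat indices plus the source row of
    each index."""
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    rows = np.repeat(np.arange(len(lo)), counts)
    starts = np.repeat(lo, counts)
    within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    return starts + within, rows


class SeedIndex:
    """13-mer seed index over a reference, with conversion-tolerant lookup.

    Chromosomes are concatenated with N spacers (k-1 wide) so no k-mer spans
    a contig boundary; positions are global and mapped back to contigs on
    output.
    """

    def __init__(self, reference: ReferenceBundle, k: int = DEFAULT_K):
        self.k = k
        self.reference = reference
        names = list(reference.sequences)
        gap = np.full(k - 1, N, dtype=np.uint8)
        parts: list[np.ndarray] = []
        offsets = []
        pos = 0
        for name in names:
            offsets.append(pos)
            seq = reference.sequences[name]
            parts.append(seq)
            parts.append(gap)
            pos += len(seq) + (k - 1)
        self.cat = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        self.chrom_names = names
        self.chrom_offsets = np.array(offsets, dtype=np.int64)
        self.chrom_lengths = np.array(
            [len(reference.sequences[n]) for n in names], dtype=np.int64
        )

        codes, valid = _kmer_codes(self.cat, k)
        positions = np.flatnonzero(valid).astype(np.int64)
        tc_codes, _ = _kmer_codes(_COLLAPSE_TC[self.cat], k)
        ag_codes, _ = _kmer_codes(_COLLAPSE_AG[self.cat], k)
        self._lookup = {
            "+": _SortedLookup(tc_codes[positions], positions),
            "-": _SortedLookup(ag_codes[positions], positions),
        }

    def global_to_local(self, gpos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self.chrom_offsets, gpos, side="right")) - 1
        return self.chrom_names[i], int(gpos - self.chrom_offsets[i])

    def seed_hits(
        self, query: np.ndarray, strand: str, conversion_aware: bool
    ) -> tuple[np.ndarray, np.ndarray]:
        """All verified (genome_pos, query_offset) seed hits of `query`
        (already reverse-complemented for the minus strand)."""
        k = self.k
        if len(query) < k:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        collapse = _COLLAPSE_TC if strand == "+" else _COLLAPSE_AG
        qcodes, _ = _kmer_codes(collapse[query], k)
        isn = np.concatenate(([0], np.cumsum(query == N)))
        qvalid = (isn[k:] - isn[:-k]) == 0
        offs = np.flatnonzero(qvalid)
        if offs.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        lo, hi = self._lookup[strand].ranges(qcodes[offs])
        idx, rows = _multirange(lo, hi)
        if idx.size == 0:
            return idx, rows
        gpos = self._lookup[strand].positions[idx]
        qoff = offs[rows]
        # verify mismatch direction: only reference-T/read-C (or A/G) allowed
        ar = np.arange(k)
        refwin = self.cat[gpos[:, None] + ar]
        qwin = query[qoff[:, None] + ar]
        mism = refwin != qwin
        if conversion_aware:
            rc, qc = conversion_pair(strand)
            ok = ~np.any(mism & ~((refwin == rc) & (qwin == qc)), axis=1)
        else:
            ok = ~np.any(mism, axis=1)
        return gpos[ok], qoff[ok]


@dataclass(frozen=True)
class CandidateMappingRegion:
    """Genome window with enough seed hits to warrant full alignment."""

    strand: str
    window_start: int  # global coordinates
    window_end: int
    diagonal: int  # dominant diagonal (global ref pos of query position 0)
    seed_count: int


@dataclass
class Mismatch:
    __slots__ = ("gpos", "ref", "read", "read_pos", "qual")
    gpos: int  # chrom-local, 0-based, genome-forward
    ref: int  # reference base code (genome forward)
    read: int  # read base code as aligned (genome forward orientation)
    read_pos: int  # position in the original read
    qual: int


@dataclass
class Alignment:
    """One candidate mapping location of a read."""

    chrom: str
    pos: int  # 0-based leftmost aligned reference position
    strand: str
    score: int
    cigar: str
    n_matches: int
    n_conversions: int  # transcript-strand T>C columns
    n_other_mismatches: int
    aligned_len: int  # aligned read bases
    ref_span: int  # aligned reference bases
    read_len: int
    mismatches: list[Mismatch] = field(default_factory=list)
    n_locations: int = 1

    @property
    def identity(self) -> float:
        """Fraction of aligned columns matching, counting T>C conversions as
        matches (the conversion is signal, not error)."""
        if self.aligned_len == 0:
            return 0.0
        return (self.n_matches + self.n_conversions) / self.aligned_len

    @property
    def identity_strict(self) -> float:
        if self.aligned_len == 0:
            return 0.0
        return self.n_matches / self.aligned_len

    @property
    def aligned_fraction(self) -> float:
        return self.aligned_len / self.read_len if self.read_len else 0.0

    @property
    def end(self) -> int:
        return self.pos + self.ref_span


@dataclass
class ReadMapping:
    name: str
    read_len: int
    status: str  # mapped | unmapped | discarded_too_many_locations
    alignments: list[Alignment] = field(default_factory=list)
    seq: np.ndarray | None = None
    qual: np.ndarray | None = None

    @property
    def best(self) -> Alignment | None:
        return self.alignments[0] if self.alignments else None


@dataclass
class MapConfig:
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    k: int = DEFAULT_K
    max_locations: int = 100
    cmr_count_fraction: float = 0.3  # keep CMRs with >= this x best seed count
    diagonal_cluster_gap: int = 8
    window_pad: int = 12
    sw_identity_trigger: float = 0.90  # gapless identity below this -> SW
    sw_aligned_fraction_trigger: float = 0.60
    sw_min_seed_count: int = 4  # SW fallback only for well-seeded CMRs
    min_report_score: int = 1


def _seed_clusters(
    query: np.ndarray,
    index: SeedIndex,
    strand: str,
    conversion_aware: bool,
    cluster_gap: int,
    window_pad: int,
) -> list[CandidateMappingRegion]:
    """All diagonal clusters of verified seed hits on one strand, without
    any count threshold applied."""
    gpos, qoff = index.seed_hits(query, strand, conversion_aware)
    if gpos.size == 0:
        return []
    diags = gpos - qoff
    order = np.argsort(diags, kind="stable")
    diags = diags[order]
    # cluster diagonals closer than cluster_gap
    breaks = np.flatnonzero(np.diff(diags) > cluster_gap)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [diags.size]))
    regions = []
    L = len(query)
    for s, e in zip(starts, ends):
        block = diags[s:e]
        vals, counts = np.unique(block, return_counts=True)
        dominant = int(vals[np.argmax(counts)])
        regions.append(
            CandidateMappingRegion(
                strand=strand,
                window_start=int(block[0]) - window_pad,
                window_end=int(block[-1]) + L + window_pad,
                diagonal=dominant,
                seed_count=int(e - s),
            )
        )
    return regions


def find_cmrs(
    query: np.ndarray,
    index: SeedIndex,
    strand: str,
    conversion_aware: bool = True,
    count_fraction: float = 0.3,
    cluster_gap: int = 8,
    window_pad: int = 12,
    best_count: int | None = None,
) -> list[CandidateMappingRegion]:
    """Candidate mapping regions on one strand: seed-hit clusters whose
    count reaches ``count_fraction`` of the best cluster's count (and is
    always >= 1).  `best_count` lets the caller supply the best count over
    both strands so spurious clusters on the opposite strand don't survive
    thresholding."""
    regions = _seed_clusters(query, index, strand, conversion_aware,
                             cluster_gap, window_pad)
    if not regions:
        return []
    best = best_count or max(r.seed_count for r in regions)
    threshold = max(1, int(np.ceil(count_fraction * best)))
    return [r for r in regions if r.seed_count >= threshold]


def _local_trim(scores: np.ndarray) -> tuple[int, int, int]:
    """Max-sum contiguous block of per-column scores, preferring the longest
    block on ties (so zero-scoring conversion columns at the edges are kept).

    Returns (start, end, score); end exclusive; score <= 0 -> empty block.
    """
    p = np.concatenate(([0], np.cumsum(scores, dtype=np.int64)))
    minacc = np.minimum.accumulate(p)
    val = p[1:] - minacc[:-1]
    best = int(val.max())
    if best <= 0:
        return 0, 0, 0
    j = len(val) - 1 - int(np.argmax(val[::-1] == best))
    m = minacc[j]
    i = int(np.argmax(p[: j + 1] == m))
    return i, j + 1, best


def _affine_sw(
    query: np.ndarray,
    ref: np.ndarray,
    matrix: np.ndarray,
    gap_open: int,
    gap_extend: int,
) -> tuple[int, int, int, int, int, list[tuple[str, int]]]:
    """Plain affine-gap Smith-Waterman with traceback.

    Returns (score, q_start, q_end, r_start, r_end, cigar ops) where cigar
    ops are [(op, length), ...] over the aligned block only.  Quadratic and
    pure Python; used only as a fallback when the gapless extension fails.
    """
    nq, nr = len(query), len(ref)
    NEG = -(10**9)
    H = np.zeros((nq + 1, nr + 1), dtype=np.int64)
    E = np.full((nq + 1, nr + 1), NEG, dtype=np.int64)  # gap in query (D)
    F = np.full((nq + 1, nr + 1), NEG, dtype=np.int64)  # gap in ref (I)
    ptr = np.zeros((nq + 1, nr + 1), dtype=np.int8)  # 0 stop 1 diag 2 up(I) 3 left(D)
    best, bi, bj = 0, 0, 0
    for i in range(1, nq + 1):
        qi = query[i - 1]
        row_m = matrix[:, qi]
        for j in range(1, nr + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open + gap_extend)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open + gap_extend)
            diag = H[i - 1][j - 1] + row_m[ref[j - 1]]
            h = max(0, diag, E[i][j], F[i][j])
            H[i][j] = h
            if h == 0:
                ptr[i][j] = 0
            elif h == diag:
                ptr[i][j] = 1
            elif h == F[i][j]:
                ptr[i][j] = 2
            else:
                ptr[i][j] = 3
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0:
        return 0, 0, 0, 0, 0, []
    ops: list[tuple[str, int]] = []
    i, j = bi, bj
    while i > 0 and j > 0 and ptr[i][j] != 0 and H[i][j] > 0:
        p = ptr[i][j]
        if p == 1:
            op = "M"
            i, j = i - 1, j - 1
        elif p == 2:
            op = "I"
            i -= 1
        else:
            op = "D"
            j -= 1
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    ops.reverse()
    return best, i, bi, j, bj, ops


def align_read(
    query: np.ndarray,
    orig_qual: np.ndarray,
    cmrs: Sequence[CandidateMappingRegion],
    index: SeedIndex,
    cfg: MapConfig,
) -> list[Alignment]:
    """Align a (strand-oriented) query against each CMR and return scored
    alignments sorted by (-score, chrom, pos)."""
    L = len(query)
    results: dict[tuple[str, str, int], Alignment] = {}
    matrices = {s: cfg.scheme.matrix(s) for s in set(c.strand for c in cmrs)}
    for cmr in cmrs:
        strand = cmr.strand
        M = matrices[strand]
        rc, qc = conversion_pair(strand)
        d = cmr.diagonal
        j0 = max(0, -d)
        j1 = min(L, len(index.cat) - d)
        if j1 <= j0:
            continue
        refwin = index.cat[d + j0 : d + j1]
        qwin = query[j0:j1]
        colscore = M[refwin, qwin]
        i, j, score = _local_trim(colscore)
        aln: Alignment | None = None
        if score > 0:
            qlo, qhi = j0 + i, j0 + j
            aln = _gapless_alignment(
                query, orig_qual, refwin[i:j], d + qlo, qlo, qhi, score,
                strand, rc, qc, index, L
            )
        needs_sw = cmr.seed_count >= cfg.sw_min_seed_count and (
            aln is None
            or aln.identity < cfg.sw_identity_trigger
            or aln.aligned_fraction < cfg.sw_aligned_fraction_trigger
        )
        if needs_sw:
            sw = _sw_alignment(query, orig_qual, cmr, index, cfg, M, rc, qc, L)
            if sw is not None and (aln is None or sw.score > aln.score):
                aln = sw
        if aln is None or aln.score < cfg.min_report_score:
            continue
        key = (aln.strand, aln.chrom, aln.pos)
        if key not in results or aln.score > results[key].score:
            results[key] = aln
    out = list(results.values())
    out.sort(key=lambda a: (-a.score, a.chrom, a.pos))
    return out


def _read_pos_and_qual(qpos: int, strand: str, L: int, orig_qual: np.ndarray) -> tuple[int, int]:
    rp = qpos if strand == "+" else L - 1 - qpos
    return rp, int(orig_qual[rp])


def _gapless_alignment(
    query, orig_qual, refblock, gstart, qlo, qhi, score, strand, rc, qc, index, L
) -> Alignment:
    qblock = query[qlo:qhi]
    mism_cols = np.flatnonzero(refblock != qblock)
    conv = (refblock[mism_cols] == rc) & (qblock[mism_cols] == qc)
    n_conv = int(conv.sum())
    n_match = int((refblock == qblock).sum())
    chrom, pos = index.global_to_local(gstart)
    mms = []
    for col in mism_cols:
        qpos = qlo + int(col)
        rp, qual = _read_pos_and_qual(qpos, strand, L, orig_qual)
        mms.append(
            Mismatch(pos + int(col), int(refblock[col]), int(qblock[col]), rp, qual)
        )
    alen = qhi - qlo
    cigar = _clip_cigar(qlo, [("M", alen)], L)
    return Alignment(
        chrom=chrom,
        pos=pos,
        strand=strand,
        score=int(score),
        cigar=cigar,
        n_matches=n_match,
        n_conversions=n_conv,
        n_other_mismatches=len(mms) - n_conv,
        aligned_len=alen,
        ref_span=alen,
        read_len=L,
        mismatches=mms,
    )


def _sw_alignment(query, orig_qual, cmr, index, cfg, M, rc, qc, L) -> Alignment | None:
    ws = max(0, cmr.window_start)
    we = min(len(index.cat), cmr.window_end)
    if we <= ws:
        return None
    ref = index.cat[ws:we]
    score, qs, qe, rs, re_, ops = _affine_sw(
        query, ref, M, cfg.scheme.gap_open, cfg.scheme.gap_extend
    )
    if score <= 0:
        return None
    chrom, pos = index.global_to_local(ws + rs)
    mms: list[Mismatch] = []
    n_match = n_conv = aligned = 0
    qi, ri = qs, rs
    for op, ln in ops:
        if op == "M":
            for t in range(ln):
                rb, qb = int(ref[ri + t]), int(query[qi + t])
                if rb == qb:
                    n_match += 1
                else:
                    rp, qual = _read_pos_and_qual(qi + t, cmr.strand, L, orig_qual)
                    mms.append(Mismatch(pos + (ri + t - rs), rb, qb, rp, qual))
                    if rb == rc and qb == qc:
                        n_conv += 1
            aligned += ln
            qi += ln
            ri += ln
        elif op == "I":
            aligned += ln
            qi += ln
        else:
            ri += ln
    cigar = _clip_cigar(qs, ops, L)
    return Alignment(
        chrom=chrom,
        pos=pos,
        strand=cmr.strand,
        score=int(score),
        cigar=cigar,
        n_matches=n_match,
        n_conversions=n_conv,
        n_other_mismatches=len(mms) - n_conv,
        aligned_len=aligned,
        ref_span=re_ - rs,
        read_len=L,
        mismatches=mms,
    )


def _clip_cigar(q_start: int, ops: Sequence[tuple[str, int]], L: int) -> str:
    used = sum(ln for op, ln in ops if op in "MI")
    parts = []
    if q_start:
        parts.append(f"{q_start}S")
    parts.extend(f"{ln}{op}" for op, ln in ops)
    tail = L - q_start - used
    if tail:
        parts.append(f"{tail}S")
    return "".join(parts)


# ------------------------------------------------------------------- mapping


def map_readset(
    reads: Iterable,
    reference: ReferenceBundle | SeedIndex,
    cfg: MapConfig | None = None,
) -> list[ReadMapping]:
    """Map a read set against a reference.

    `reads` yields (name, seq_codes, qual) tuples or objects with .name,
    .seq, .qual attributes.  Returns one ReadMapping per input read, in
    input order; multimapping reads carry all reported locations (capped at
    cfg.max_locations; beyond that the read is discarded).
    """
    cfg = cfg or MapConfig()
    index = reference if isinstance(reference, SeedIndex) else SeedIndex(reference, cfg.k)
    out: list[ReadMapping] = []
    aware = cfg.scheme.conversion_aware
    for item in reads:
        if isinstance(item, tuple):
            name, seq, qual = item
        else:
            name, seq, qual = item.name, item.seq, item.qual
        L = len(seq)
        mapping = ReadMapping(name=name, read_len=L, status="unmapped", seq=seq, qual=qual)
        if L >= cfg.k:
            queries = {"+": seq, "-": revcomp(seq)}
            clusters = {
                s: _seed_clusters(q, index, s, aware,
                                  cfg.diagonal_cluster_gap, cfg.window_pad)
                for s, q in queries.items()
            }
            best = max(
                (c.seed_count for cs in clusters.values() for c in cs), default=0
            )
            threshold = max(1, int(np.ceil(cfg.cmr_count_fraction * best)))
            alignments: list[Alignment] = []
            for strand, query in queries.items():
                cmrs = [c for c in clusters[strand] if c.seed_count >= threshold]
                alignments.extend(align_read(query, qual, cmrs, index, cfg))
            alignments.sort(key=lambda a: (-a.score, a.chrom, a.pos))
            if len(alignments) > cfg.max_locations:
                mapping.status = "discarded_too_many_locations"
            elif alignments:
                mapping.status = "mapped"
                for a in alignments:
                    a.n_locations = len(alignments)
                mapping.alignments = alignments
        out.append(mapping)
    return out


# ----------------------------------------------------------------------- SAM

# Custom tags (see README): Xc = T>C conversion count, Xm = encoded mismatch
# list "pos,ref,read,readpos,qual;...", Xd = discard reason.


def _sam_header(reference: ReferenceBundle) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": name, "LN": len(seq)}
                for name, seq in reference.sequences.items()
            ],
        }
    )


def mappings_to_sam(
    mappings: Sequence[ReadMapping],
    reference: ReferenceBundle,
    path: str | Path,
) -> None:
    """Write mappings to SAM (or, for a .bam path, coordinate-sorted and
    indexed BAM), one record per reported location (secondary records
    flagged), unmapped/discarded reads as unmapped records."""
    path = str(path)
    if path.endswith(".bam"):
        import tempfile, os

        with tempfile.TemporaryDirectory() as tmp:
            raw = os.path.join(tmp, "unsorted.sam")
            mappings_to_sam(mappings, reference, raw)
            pysam.sort("-o", path, raw)
        pysam.index(path)
        return
    header = _sam_header(reference)
    refids = {name: i for i, name in enumerate(reference.sequences)}
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for m in mappings:
            if not m.alignments:
                rec = pysam.AlignedSegment(header)
                rec.query_name = m.name
                rec.is_unmapped = True
                if m.seq is not None:
                    rec.query_sequence = "".join(BASES[c] for c in m.seq)
                    rec.query_qualities = pysam.qualitystring_to_array(
                        "".join(chr(q + 33) for q in m.qual)
                    )
                if m.status == "discarded_too_many_locations":
                    rec.set_tag("Xd", "too_many_locations")
                fh.write(rec)
                continue
            for rank, a in enumerate(m.alignments):
                rec = pysam.AlignedSegment(header)
                rec.query_name = m.name
                rec.reference_id = refids[a.chrom]
                rec.reference_start = a.pos
                rec.cigarstring = a.cigar
                rec.is_reverse = a.strand == "-"
                rec.is_secondary = rank > 0
                rec.mapping_quality = 0 if a.n_locations > 1 else 60
                if m.seq is not None:
                    oriented = m.seq if a.strand == "+" else revcomp(m.seq)
                    qual = m.qual if a.strand == "+" else m.qual[::-1]
                    rec.query_sequence = "".join(BASES[c] for c in oriented)
                    rec.query_qualities = pysam.qualitystring_to_array(
                        "".join(chr(q + 33) for q in qual)
                    )
                rec.set_tag("AS", a.score)
                rec.set_tag("NH", a.n_locations)
                rec.set_tag("Xc", a.n_conversions)
                rec.set_tag(
                    "Xm",
                    ";".join(
                        f"{mm.gpos},{BASES[mm.ref]},{BASES[mm.read]},{mm.read_pos},{mm.qual}"
                        for mm in a.mismatches
                    ),
                )
                fh.write(rec)


def sam_to_mappings(path: str | Path) -> list[ReadMapping]:
    """Reconstruct ReadMapping objects from a SAM/BAM written by
    mappings_to_sam (grouping records by read name)."""
    grouped: dict[str, ReadMapping] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            name = rec.query_name
            if name not in grouped:
                L = rec.query_length or (len(rec.query_sequence or ""))
                status = "unmapped"
                if rec.has_tag("Xd"):
                    status = "discarded_too_many_locations"
                grouped[name] = ReadMapping(name=name, read_len=L, status=status)
                order.append(name)
            m = grouped[name]
            if rec.is_unmapped:
                continue
            strand = "-" if rec.is_reverse else "+"
            mms = []
            tag = rec.get_tag("Xm") if rec.has_tag("Xm") else ""
            if tag:
                for part in tag.split(";"):
                    p, rb, qb, rp, q = part.split(",")
                    mms.append(
                        Mismatch(int(p), BASES.index(rb), BASES.index(qb), int(rp), int(q))
                    )
            aligned = sum(ln for op, ln in rec.cigartuples if op in (0, 1, 7, 8))
            ref_span = sum(ln for op, ln in rec.cigartuples if op in (0, 2, 7, 8))
            rc, qc = conversion_pair(strand)
            n_conv = int(rec.get_tag("Xc")) if rec.has_tag("Xc") else sum(
                1 for mm in mms if mm.ref == rc and mm.read == qc
            )
            L = m.read_len or aligned
            a = Alignment(
                chrom=rec.reference_name,
                pos=rec.reference_start,
                strand=strand,
                score=int(rec.get_tag("AS")) if rec.has_tag("AS") else 0,
                cigar=rec.cigarstring or "",
                n_matches=aligned - len(mms),
                n_conversions=n_conv,
                n_other_mismatches=len(mms) - n_conv,
                aligned_len=aligned,
                ref_span=ref_span,
                read_len=L,
                mismatches=mms,
                n_locations=int(rec.get_tag("NH")) if rec.has_tag("NH") else 1,
            )
            m.alignments.append(a)
            m.status = "mapped"
    for m in grouped.values():
        m.alignments.sort(key=lambda a: (-a.score, a.chrom, a.pos))
    return [grouped[n] for n in order]
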