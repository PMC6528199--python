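"""Synthetic SLAMseq data with planted ground truth.

Builds fully synthetic references (no external genome needed) and simulates
stranded, unspliced 3' end sequencing reads from them, following the
metabolic-labeling model: a fraction ``p_SU`` of each interval's transcripts
is 4SU-labeled, and each labeled read acquires ``Binomial(t, p_e)`` T>C
conversions at uniformly chosen T positions, where ``t`` is the number of
thymidines in the read (transcript strand) and ``p_e`` the per-T conversion
efficiency.  Homozygous SNPs are planted into the *sample* genome at a
configurable rate while the reference stays clean, so SNPs surface as
consistent mismatches exactly as they do in real data.

Only the terminal 250 bp of each interval is used for simulation, mimicking
QuantSeq 3' end coverage.  Every read name encodes its origin interval, its
labeled status and the number of conversions planted, so every downstream
stage can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    A,
    C,
    G,
    T,
    N,
    BASES,
    Interval,
    ReferenceBundle,
    decode,
    revcomp,
    write_bed,
    write_fasta,
)

TERMINAL_WINDOW = 250  # bp of each 3' interval actually sequenced

# ------------------------------------------------------------------ reference


@dataclass
class SyntheticGenomeSpec:
    """Parameters of a synthetic reference genome.

    duplication_fraction controls how many intervals receive a near-identical
    (~98% identity) copy elsewhere in the genome, to exercise multimapper
    recovery; duplicate_into_annotation_fraction is the share of those copies
    that are themselves annotated as 3' intervals (reads from these become
    genuinely ambiguous and must be discarded).
    """

    n_intervals: int = 100
    interval_length: tuple[int, int] = (250, 4000)  # uniform range, bp
    t_fraction: float = 0.25  # transcript-strand per-base T probability
    # per-interval T fraction drawn uniformly from this range instead of the
    # single t_fraction, emulating the U-content variation of real 3' UTRs
    t_fraction_range: tuple[float, float] | None = None
    duplication_fraction: float = 0.0
    duplicate_into_annotation_fraction: float = 0.0
    snp_rate: float = 0.001  # per-base homozygous SNP probability
    spacer_length: int = 150  # random sequence between intervals
    copy_identity: float = 0.98  # identity of duplicated copies
    seed: int = 0
    genome_size_cap: int = 50_000_000  # bp

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_fraction <= 1.0:
            raise ValueError("t_fraction must be in [0, 1]")
        if not 0.0 <= self.duplication_fraction <= 1.0:
            raise ValueError("duplication_fraction must be in [0, 1]")
        if self.snp_rate < 0.0:
            raise ValueError("snp_rate must be >= 0")
        if self.n_intervals * self.interval_length[1] > self.genome_size_cap:
            raise ValueError(
                f"{self.n_intervals} intervals of up to {self.interval_length[1]} bp "
                f"exceed the genome size cap of {self.genome_size_cap} bp"
            )


@dataclass(frozen=True)
class PlantedSnp:
    chrom: str
    pos: int  # 0-based
    ref: int  # base code
    alt: int  # base code


@dataclass
class SyntheticReference:
    """A clean reference plus the SNP-mutated sample genome it was read from."""

    reference: ReferenceBundle
    sample_sequences: dict[str, np.ndarray]
    snps: list[PlantedSnp]
    duplicated_outside: list[str] = field(default_factory=list)
    duplicated_into_annotation: list[str] = field(default_factory=list)

    def write(self, fasta: str | Path, bed: str | Path, vcf: str | Path) -> None:
        self.reference.write(fasta, bed)
        write_truth_vcf(vcf, self.snps, self.reference.sequences)


def _random_transcript(rng: np.random.Generator, length: int, t_fraction: float) -> np.ndarray:
    other = (1.0 - t_fraction) / 3.0
    return rng.choice(4, size=length, p=[other, other, other, t_fraction]).astype(np.uint8)


def _mutate_copy(rng: np.random.Generator, seq: np.ndarray, identity: float) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < (1.0 - identity))
    for i in hits:
        out[i] = (out[i] + rng.integers(1, 4)) % 4
    return out


def generate_synthetic_reference(spec: SyntheticGenomeSpec) -> SyntheticReference:
    """Build a single-contig genome of alternating-strand 3' intervals
    separated by random spacers, optionally with duplicated intervals, and
    plant homozygous SNPs into a sample copy.

    Deterministic for a given spec (same seed => byte-identical outputs).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.interval_length
    pieces: list[np.ndarray] = []
    intervals: list[Interval] = []
    pos = 0

    def spacer() -> None:
        nonlocal pos
        s = rng.integers(0, 4, size=spec.spacer_length).astype(np.uint8)
        pieces.append(s)
        pos += len(s)

    interval_seqs: list[np.ndarray] = []  # genome-strand sequences, for copies
    for i in range(spec.n_intervals):
        spacer()
        length = int(rng.integers(lo, hi + 1))
        strand = "+" if i % 2 == 0 else "-"
        if spec.t_fraction_range is not None:
            t_lo, t_hi = spec.t_fraction_range
            tf = float(rng.uniform(t_lo, t_hi))
        else:
            tf = spec.t_fraction
        transcript = _random_transcript(rng, length, tf)
        genomic = transcript if strand == "+" else revcomp(transcript)
        name = f"ivl{i:05d}"
        intervals.append(Interval("chrS", pos, pos + length, name, strand))
        pieces.append(genomic)
        interval_seqs.append(genomic)
        pos += length

    # duplicated copies go into a trailing zone; a subset is annotated
    n_dup = int(round(spec.duplication_fraction * spec.n_intervals))
    dup_idx = rng.choice(spec.n_intervals, size=n_dup, replace=False) if n_dup else []
    n_into = int(round(spec.duplicate_into_annotation_fraction * n_dup))
    duplicated_outside: list[str] = []
    duplicated_into: list[str] = []
    for j, idx in enumerate(sorted(int(x) for x in dup_idx)):
        spacer()
        src = intervals[idx]
        copy = _mutate_copy(rng, interval_seqs[idx], spec.copy_identity)
        if j < n_into:
            intervals.append(
                Interval("chrS", pos, pos + len(copy), f"{src.name}_copy", src.strand)
            )
            duplicated_into.append(src.name)
        else:
            duplicated_outside.append(src.name)
        pieces.append(copy)
        pos += len(copy)
    spacer()

    genome = np.concatenate(pieces)
    reference = ReferenceBundle({"chrS": genome}, intervals)

    sample, raw_snps = plant_snps(genome, spec.snp_rate, rng)
    snps = [PlantedSnp("chrS", p, r, a) for p, r, a in raw_snps]
    return SyntheticReference(reference, {"chrS": sample}, snps,
                              duplicated_outside, duplicated_into)


def plant_snps(
    sequence: np.ndarray, snp_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Mutate each non-N base to a uniformly chosen different base with
    probability ``snp_rate``; returns (mutated copy, [(pos, ref, alt), ...])."""
    out = sequence.copy()
    snps: list[tuple[int, int, int]] = []
    if snp_rate <= 0:
        return out, snps
    hits = np.flatnonzero((rng.random(len(sequence)) < snp_rate) & (sequence != N))
    for p in hits:
        ref = int(sequence[p])
        alt = (ref + int(rng.integers(1, 4))) % 4
        out[p] = alt
        snps.append((int(p), ref, alt))
    return out, snps


# ------------------------------------------------------------------ intervals


def deoverlap_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Remove every member of each same-strand overlap group.

    Dropping the whole group (rather than keeping one survivor) keeps the
    truth assignment of simulated reads unambiguous.
    """
    order = sorted(range(len(intervals)), key=lambda i: (
        intervals[i].chrom, intervals[i].strand, intervals[i].start))
    drop: set[int] = set()
    group: list[int] = []
    group_end = -1
    prev_key: tuple[str, str] | None = None

    def flush() -> None:
        if len(group) > 1:
            drop.update(group)

    for i in order:
        iv = intervals[i]
        key = (iv.chrom, iv.strand)
        if key != prev_key or iv.start >= group_end:
            flush()
            group = [i]
            group_end = iv.end
            prev_key = key
        else:
            group.append(i)
            group_end = max(group_end, iv.end)
    flush()
    return [iv for i, iv in enumerate(intervals) if i not in drop]


def assign_labeled_fractions(
    intervals: Sequence[Interval],
    mode: str = "uniform",
    value: float | None = None,
    table: dict[str, float] | None = None,
    rng: np.random.Generator | int | None = None,
) -> dict[str, float]:
    """Assign a labeled-transcript fraction p_SU in [0, 1] to every interval.

    mode: 'uniform' (p_SU ~ U(0,1), seeded), 'fixed' (all intervals get
    `value`), or 'table' (explicit per-interval values).
    """
    if mode == "fixed":
        if value is None or not 0.0 <= value <= 1.0:
            raise ValueError("fixed mode requires a value in [0, 1]")
        return {iv.name: float(value) for iv in intervals}
    if mode == "uniform":
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        draws = gen.random(len(intervals))
        return {iv.name: float(p) for iv, p in zip(intervals, draws)}
    if mode == "table":
        if table is None:
            raise ValueError("table mode requires a table")
        out = {}
        for iv in intervals:
            if iv.name not in table:
                raise KeyError(f"no labeled fraction supplied for interval {iv.name}")
            out[iv.name] = float(table[iv.name])
        return out
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------- reads


@dataclass
class SimulatedRead:
    name: str
    seq: np.ndarray  # transcript orientation, code array
    qual: np.ndarray  # Phred scores
    interval: str
    labeled: bool
    n_conversions: int
    chrom: str
    gstart: int  # genomic start of the true origin (0-based)
    strand: str


def make_read_name(interval: str, idx: int, labeled: bool, n_conversions: int) -> str:
    return f"{interval}:{idx}:{'L' if labeled else 'U'}:{n_conversions}"


def parse_read_name(name: str) -> tuple[str, int, bool, int]:
    interval, idx, flag, nconv = name.rsplit(":", 3)
    return interval, int(idx), flag == "L", int(nconv)


class _TruncatedBinomial:
    """Binomial(t, p) conditioned on k >= k_min, with the pmf cached per t."""

    def __init__(self, p: float, k_min: int):
        self.p = p
        self.k_min = k_min
        self._cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def draw(self, rng: np.random.Generator, t: int) -> int:
        if self.k_min <= 0:
            return int(rng.binomial(t, self.p))
        if t <= self.k_min:
            return t  # conditioning forces every T converted
        if t not in self._cache:
            ks = np.arange(self.k_min, t + 1)
            pmf = stats.binom.pmf(ks, t, self.p)
            self._cache[t] = (ks, pmf / pmf.sum())
        ks, probs = self._cache[t]
        return int(rng.choice(ks, p=probs))


def simulate_reads(
    window_seq: np.ndarray,
    p_su: float,
    p_e: float,
    coverage: float,
    read_length: int,
    error_rate: float = 0.001,
    rng: np.random.Generator | int | None = None,
    min_conversions: int = 0,
    bad_cycles: Sequence[int] = (),
    bad_cycle_error_rate: float = 0.05,
    base_quality: int = 30,
    bad_cycle_quality: int = 10,
    error_quality: int = 10,
) -> tuple[list[tuple[np.ndarray, np.ndarray, bool, int, int]], int]:
    """Simulate reads from a (transcript-orientation) window sequence.

    Returns ([(seq, qual, labeled, n_conversions, start_offset), ...], n_reads).
    Conversions are planted before sequencing errors; the recorded conversion
    count is the planted number.
    """
    w = len(window_seq)
    if read_length > w:
        raise ValueError(f"read length {read_length} exceeds window of {w} bp")
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n_reads = max(1, int(round(coverage * w / read_length)))
    starts = gen.integers(0, w - read_length + 1, size=n_reads)
    labeled = gen.random(n_reads) < p_su

    quals = np.full(read_length, base_quality, dtype=np.int16)
    bad = np.asarray(sorted(set(int(b) for b in bad_cycles if 0 <= b < read_length)), dtype=int)
    if bad.size:
        quals[bad] = bad_cycle_quality
    err_p = np.full(read_length, error_rate)
    if bad.size:
        err_p[bad] = bad_cycle_error_rate

    out = []
    binom = _TruncatedBinomial(p_e, min_conversions)
    for i in range(n_reads):
        s = int(starts[i])
        seq = window_seq[s : s + read_length].copy()
        k = 0
        if labeled[i] and p_e > 0:
            t_pos = np.flatnonzero(seq == T)
            if len(t_pos) > 0:
                k = binom.draw(gen, len(t_pos))
                if k > 0:
                    conv = gen.choice(t_pos, size=k, replace=False)
                    seq[conv] = C
        # uniform sequencing errors (may hit converted positions); miscalled
        # bases carry low reported quality, as real miscalls tend to, so the
        # base-quality filter downstream has the same handle it has on real data
        errs = np.flatnonzero(gen.random(read_length) < err_p)
        q = quals.copy()
        for e in errs:
            seq[e] = (seq[e] + gen.integers(1, 4)) % 4
            q[e] = min(q[e], error_quality)
        out.append((seq, q, bool(labeled[i]), k, s))
    return out, n_reads


@dataclass
class SimulatedDataset:
    reads: list[SimulatedRead]
    truth: pd.DataFrame  # per interval: n_reads, n_labeled, p_su, p_e
    p_su: dict[str, float]
    p_e: float

    def write_fastq(self, path: str | Path) -> None:
        write_fastq(path, self.reads)

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def simulate_dataset(
    ref: SyntheticReference,
    p_su: dict[str, float] | float,
    p_e: float,
    coverage: float = 100.0,
    read_length: int = 100,
    error_rate: float = 0.001,
    seed: int | None = 0,
    min_conversions: int = 0,
    bad_cycles: Sequence[int] = (),
    bad_cycle_error_rate: float = 0.05,
) -> SimulatedDataset:
    """Simulate a full dataset over every annotated interval of `ref`.

    Reads are drawn from the SNP-mutated sample genome, restricted to the
    terminal 250 bp of each interval, in transcript orientation.
    """
    rng = np.random.default_rng(seed)
    bundle = ref.reference
    if isinstance(p_su, (int, float)):
        p_su = {iv.name: float(p_su) for iv in bundle.intervals}
    reads: list[SimulatedRead] = []
    rows = []
    for iv in bundle.intervals:
        if iv.name not in p_su:
            continue
        win_start, win_end = bundle.terminal_window(iv, TERMINAL_WINDOW)
        gslice = ref.sample_sequences[iv.chrom][win_start:win_end]
        window = revcomp(gslice) if iv.strand == "-" else gslice
        if len(window) < read_length:
            raise ValueError(
                f"interval {iv.name} window ({len(window)} bp) shorter than read length"
            )
        sim, n = simulate_reads(
            window,
            p_su[iv.name],
            p_e,
            coverage,
            read_length,
            error_rate=error_rate,
            rng=rng,
            min_conversions=min_conversions,
            bad_cycles=bad_cycles,
            bad_cycle_error_rate=bad_cycle_error_rate,
        )
        n_labeled = 0
        for j, (seq, qual, lab, k, s) in enumerate(sim):
            n_labeled += lab
            if iv.strand == "+":
                gstart = win_start + s
            else:
                gstart = win_end - s - read_length
            reads.append(
                SimulatedRead(
                    name=make_read_name(iv.name, j, lab, k),
                    seq=seq,
                    qual=qual,
                    interval=iv.name,
                    labeled=lab,
                    n_conversions=k,
                    chrom=iv.chrom,
                    gstart=gstart,
                    strand=iv.strand,
                )
            )
        rows.append((iv.name, n, n_labeled, p_su[iv.name], p_e))
    truth = pd.DataFrame(
        rows, columns=["interval", "n_reads", "n_labeled_reads", "p_su", "p_e"]
    )
    return SimulatedDataset(reads, truth, dict(p_su), p_e)


# ------------------------------------------------------------------------- io


def write_fastq(path: str | Path, reads: Iterable[SimulatedRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qual)
            fh.write(f"@{r.name}\n{decode(r.seq)}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Minimal FASTQ reader returning (name, seq codes, phred scores)."""
    from .genome import encode

    out = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            if not header.startswith("@") or len(seq) != len(qual):
                raise ValueError(f"{path}: malformed FASTQ record at {header.strip()!r}")
            out.append(
                (
                    header[1:].strip().split()[0],
                    encode(seq),
                    np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int16) - 33,
                )
            )
    return out


def write_truth_vcf(
    path: str | Path, snps: Sequence[PlantedSnp], sequences: dict[str, np.ndarray]
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in sequences.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for s in sorted(snps, key=lambda x: (x.chrom, x.pos)):
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t.\t{BASES[s.ref]}\t{BASES[s.alt]}"
                f"\t.\tPASS\t.\tGT\t1/1\n"
            )
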