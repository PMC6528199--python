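"""SNP calling, masking and the rank-enrichment diagnostic.

Reads covering a genuine T>C SNP look exactly like labeled reads, so the
pipeline calls SNPs directly from the filtered alignments with a simple
variant-fraction rule: a position is a SNP if it is covered by at least
``min_coverage`` reads and a single alternative base accounts for at least
``min_variant_fraction`` of them (default 10x / 0.8, calibrated for
haploid-derived lines where SNPs are fully penetrant; diploid samples need
a lower fraction, around 0.2-0.5 for heterozygous sites).  Called and/or
user-supplied SNP positions are masked from conversion counting.

The barcode/rank diagnostic orders intervals by their T>C read count and
asks (Mann-Whitney U) whether SNP-containing intervals concentrate at the
top; after masking the association should vanish.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import Mismatch
from .filtering import AssignedRead
from .genome import BASES, ReferenceBundle
from .scoring import conversion_pair


@dataclass
class VariantCallConfig:
    min_coverage: int = 10
    min_variant_fraction: float = 0.8
    min_base_quality: int = 13

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_variant_fraction <= 1.0:
            raise ValueError("min_variant_fraction must be in [0, 1]")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


@dataclass(frozen=True)
class Snp:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    provenance: str = "called"  # called | user_vcf


class SnpMask:
    """Set of masked genomic positions with their ref/alt bases."""

    def __init__(self, snps: Iterable[Snp] = ()):
        self.snps: dict[tuple[str, int], Snp] = {}
        for s in snps:
            self.snps[(s.chrom, s.pos)] = s

    def __len__(self) -> int:
        return len(self.snps)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.snps

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SnpMask) and set(self.snps) == set(other.snps)

    def add(self, snp: Snp) -> None:
        self.snps[(snp.chrom, snp.pos)] = snp

    def merge(self, other: "SnpMask") -> "SnpMask":
        out = SnpMask(self.snps.values())
        for s in other.snps.values():
            out.add(s)
        return out

    def positions(self, chrom: str) -> np.ndarray:
        return np.array(sorted(p for c, p in self.snps if c == chrom), dtype=np.int64)

    # ------------------------------------------------------------------ io

    @classmethod
    def from_vcf(cls, path: str | Path, provenance: str = "user_vcf") -> "SnpMask":
        import pysam

        mask = cls()
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                for alt in rec.alts or ():
                    if len(rec.ref) == 1 and len(alt) == 1:  # SNVs only
                        mask.add(Snp(rec.chrom, rec.pos - 1, rec.ref, alt, provenance))
        return mask

    def to_vcf(self, path: str | Path, reference: ReferenceBundle | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            if reference is not None:
                for name, seq in reference.sequences.items():
                    fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
            for (chrom, pos), s in sorted(self.snps.items()):
                fh.write(
                    f"{chrom}\t{pos + 1}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t1/1\n"
                )


# -------------------------------------------------------------------- pileup


def call_snps(
    assigned: Sequence[AssignedRead],
    reference: ReferenceBundle,
    cfg: VariantCallConfig | None = None,
) -> SnpMask:
    """Variant-fraction SNP calling over the assigned read set.

    Coverage is accumulated from aligned reference spans; alternative-base
    counts come from the alignments' mismatch lists (bases below
    min_base_quality are ignored).  A position is called when coverage >=
    min_coverage and one alt base reaches min_variant_fraction of the
    coverage.
    """
    cfg = cfg or VariantCallConfig()
    cov: dict[str, np.ndarray] = {}
    alt: dict[str, np.ndarray] = {}
    for name, seq in reference.sequences.items():
        cov[name] = np.zeros(len(seq) + 1, dtype=np.int32)  # diff array
        alt[name] = np.zeros((4, len(seq)), dtype=np.int32)
    for r in assigned:
        a = r.alignment
        if a.chrom not in cov:
            raise KeyError(
                f"alignment contig {a.chrom!r} not in reference "
                f"({', '.join(cov)})"
            )
        cov[a.chrom][a.pos] += 1
        cov[a.chrom][a.end] -= 1
        for mm in a.mismatches:
            if mm.qual >= cfg.min_base_quality and mm.read < 4:
                alt[a.chrom][mm.read, mm.gpos] += 1
    mask = SnpMask()
    for chrom, diffs in cov.items():
        coverage = np.cumsum(diffs[:-1])
        counts = alt[chrom]
        best_alt = counts.max(axis=0)
        candidates = np.flatnonzero(
            (coverage >= cfg.min_coverage)
            & (best_alt > 0)
            & (best_alt >= cfg.min_variant_fraction * coverage)
        )
        seq = reference.sequences[chrom]
        for p in candidates:
            b = int(np.argmax(counts[:, p]))
            if b == seq[p]:
                continue
            mask.add(Snp(chrom, int(p), BASES[int(seq[p])], BASES[b], "called"))
    return mask


def apply_mask(
    mismatches: Iterable[Mismatch], chrom: str, mask: SnpMask
) -> list[Mismatch]:
    """Drop mismatch events at masked genomic positions."""
    return [mm for mm in mismatches if (chrom, mm.gpos) not in mask.snps]


def is_conversion(mm: Mismatch, strand: str) -> bool:
    rc, qc = conversion_pair(strand)
    return mm.ref == rc and mm.read == qc


# ---------------------------------------------------------- rank enrichment


@dataclass
class RankEnrichment:
    statistic: float
    p_value: float
    barcode_positions: np.ndarray  # ranks (0 = highest T>C count) of SNP intervals
    n_intervals: int
    n_snp_intervals: int
    defined: bool = True


def snp_rank_enrichment(
    tc_counts: pd.Series,
    snp_flags: pd.Series,
    coverage: pd.Series | None = None,
    coverage_quantile: float = 0.75,
) -> RankEnrichment:
    """Mann-Whitney U test for enrichment of SNP-containing intervals among
    intervals with high T>C read counts.

    Only intervals in the upper coverage quartile are used (when coverage
    is given), so that SNP calls are not coverage-biased.  Returns the
    two-sided p-value and the rank positions for barcode plotting.
    """
    idx = tc_counts.index
    snp_flags = snp_flags.reindex(idx).fillna(False).astype(bool)
    if coverage is not None:
        floor = coverage.reindex(idx).quantile(coverage_quantile)
        keep = coverage.reindex(idx) >= floor
        tc_counts, snp_flags = tc_counts[keep], snp_flags[keep]
    order = tc_counts.sort_values(ascending=False, kind="stable").index
    rank = pd.Series(np.arange(len(order)), index=order)
    snp_ranks = rank[snp_flags.reindex(order)].to_numpy()
    other_ranks = rank[~snp_flags.reindex(order)].to_numpy()
    if len(snp_ranks) < 2 or len(other_ranks) < 2:
        return RankEnrichment(np.nan, np.nan, snp_ranks, len(rank), len(snp_ranks), False)
    # ranks computed on counts; test on the counts themselves (ties handled)
    u = stats.mannwhitneyu(
        tc_counts[snp_flags], tc_counts[~snp_flags], alternative="two-sided"
    )
    return RankEnrichment(
        float(u.statistic), float(u.pvalue), snp_ranks, len(rank), len(snp_ranks)
    )


def barcode_plot(enrichment: RankEnrichment, ax=None):
    """Barcode plot of SNP-interval ranks (black bars on the ranked axis)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 1.5))
    ax.vlines(enrichment.barcode_positions, 0, 1, colors="black", linewidth=0.5)
    ax.set_xlim(-0.5, enrichment.n_intervals - 0.5)
    ax.set_yticks([])
    ax.set_xlabel("3' intervals ranked by T>C read count")
    return ax
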