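"""T>C conversion counting and labeled-transcript-fraction estimation.

Per 3' interval the pipeline accumulates

* ``n``      - assigned reads,
* ``R_TC``   - reads with at least ``conversion_threshold`` unmasked,
  base-quality-passing T>C conversions,
* ``k_i``/``c_i`` - per transcript-strand T position, the number of reads
  converted at / covering that position (masked T positions are excluded
  from both).

Two estimators of the labeled fraction p_SU follow.  The read-count based
one models the probability that a labeled read shows no conversion,
p_0 = (1 - p_e)^t with t thymidines per read, so p_TC = 1 - p_0 and

    p_SU = (1 / p_TC) * (R_TC / n).

The T-content and coverage normalized estimator drops the "same t for
every read" idealization and works per T position: k_i ~ Binomial(c_i,
p_SU * p_e), whose pooled maximum-likelihood estimate gives

    p_SU = (1 / p_e) * (sum_i k_i / sum_i c_i).

Both clamp to [0, 1] with an explicit flag.  The module also provides the
experiment-design helper: the expected number of labeled T>C reads is
E_SU = p_SU * p_TC * n, and with empirical detection sensitivity S the
probability of seeing at least one is p_DETECT = 1 - (1 - S)^ceil(E_SU).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .filtering import AssignedRead
from .genome import A, T, Interval, ReferenceBundle
from .variants import SnpMask, is_conversion


@dataclass
class ConversionModel:
    """Read-level conversion model: t thymidines, per-T efficiency p_e."""

    p_e: float
    t: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_e <= 1.0:
            raise ValueError("p_e must be in [0, 1]")
        if self.t < 0:
            raise ValueError("t must be >= 0")

    @property
    def p_0(self) -> float:
        return (1.0 - self.p_e) ** self.t

    @property
    def p_tc(self) -> float:
        return 1.0 - self.p_0


@dataclass
class IntervalQuant:
    """Per-interval conversion counters and derived estimates."""

    interval: str
    n: int = 0  # assigned reads
    r_tc: int = 0  # reads with >= threshold conversions
    n_conversion_events: int = 0  # total counted T>C columns
    k: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    c: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    t_positions: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    t_count: int = 0  # Ts in the terminal window (unmasked)

    @property
    def sum_k(self) -> int:
        return int(self.k.sum())

    @property
    def sum_c(self) -> int:
        return int(self.c.sum())


@dataclass
class FractionEstimate:
    value: float
    clamped: bool = False
    defined: bool = True


def _clamp(x: float) -> FractionEstimate:
    if x < 0.0:
        return FractionEstimate(0.0, True)
    if x > 1.0:
        return FractionEstimate(1.0, True)
    return FractionEstimate(float(x))


def read_based_fraction(r_tc: int, n: int, p_tc: float) -> FractionEstimate:
    """p_SU from T>C read counts: (R_TC / n) / p_TC."""
    if n <= 0:
        return FractionEstimate(math.nan, defined=False)
    if not 0.0 < p_tc <= 1.0:
        raise ValueError("p_tc must be in (0, 1]")
    return _clamp(r_tc / (n * p_tc))


def tcontent_fraction(
    k: np.ndarray | Sequence[int], c: np.ndarray | Sequence[int], p_e: float
) -> FractionEstimate:
    """p_SU from per-T-position counts: (sum k / sum c) / p_e."""
    if not 0.0 < p_e <= 1.0:
        raise ValueError("p_e must be in (0, 1]")
    sk = float(np.sum(k))
    sc = float(np.sum(c))
    if sc <= 0:
        return FractionEstimate(math.nan, defined=False)
    return _clamp((sk / sc) / p_e)


def estimate_pe(quants: Sequence[IntervalQuant]) -> float:
    """Pooled conversion-efficiency estimate from a saturating-label sample
    (asserted p_SU = 1): p_e = sum k / sum c over all intervals."""
    sk = sum(q.sum_k for q in quants)
    sc = sum(q.sum_c for q in quants)
    if sc <= 0:
        raise ValueError("no T-position coverage; cannot estimate p_e")
    return sk / sc


# ------------------------------------------------------------------ counting


def count_conversions(
    assigned: Sequence[AssignedRead],
    reference: ReferenceBundle,
    mask: SnpMask | None = None,
    min_base_quality: int = 27,
    conversion_threshold: int = 1,
    window: int = 250,
) -> dict[str, IntervalQuant]:
    """Count T>C conversions per interval over the assigned read set.

    A read contributes to R_TC when it carries >= conversion_threshold
    unmasked transcript-strand T>C mismatches with base quality >=
    min_base_quality (threshold 2 suppresses background from SNPs and
    errors almost completely, at a sensitivity cost).  k_i / c_i are
    accumulated over the unmasked T positions of each interval's terminal
    window.
    """
    mask = mask or SnpMask()
    quants: dict[str, IntervalQuant] = {}
    meta: dict[str, tuple[int, int, np.ndarray, str]] = {}
    for iv in reference.intervals:
        ws, we = reference.terminal_window(iv, window)
        seq = reference.sequences[iv.chrom][ws:we]
        tbase = T if iv.strand == "+" else A  # transcript-strand T in fwd coords
        tpos = ws + np.flatnonzero(seq == tbase)
        if len(mask):
            masked = mask.positions(iv.chrom)
            if masked.size:
                tpos = tpos[~np.isin(tpos, masked)]
        q = IntervalQuant(
            interval=iv.name,
            k=np.zeros(len(tpos), dtype=np.int64),
            c=np.zeros(len(tpos), dtype=np.int64),
            t_positions=tpos,
            t_count=len(tpos),
        )
        quants[iv.name] = q
        meta[iv.name] = (ws, we, tpos, iv.chrom)
    skipped = 0
    for r in assigned:
        if r.interval not in quants:
            skipped += 1
            continue
        q = quants[r.interval]
        ws, we, tpos, chrom = meta[r.interval]
        a = r.alignment
        q.n += 1
        # coverage over T positions within the aligned reference span
        lo = np.searchsorted(tpos, a.pos)
        hi = np.searchsorted(tpos, a.end)
        q.c[lo:hi] += 1
        n_conv = 0
        for mm in a.mismatches:
            if (
                is_conversion(mm, a.strand)
                and mm.qual >= min_base_quality
                and (chrom, mm.gpos) not in mask.snps
            ):
                n_conv += 1
                j = np.searchsorted(tpos, mm.gpos)
                if j < len(tpos) and tpos[j] == mm.gpos:
                    q.k[j] += 1
        q.n_conversion_events += n_conv
        if n_conv >= conversion_threshold:
            q.r_tc += 1
    return quants


def quant_table(
    quants: dict[str, IntervalQuant],
    reference: ReferenceBundle,
    p_e: float | None = None,
    read_length: int | None = None,
    t_per_read: int | None = None,
    window: int = 250,
) -> pd.DataFrame:
    """Per-interval tcount table with both labeled-fraction estimates.

    The read-based estimator idealizes t (thymidines per read) as a single
    experiment-wide constant — that is precisely its weakness on 3'
    intervals of unusual U-content.  It defaults to round(read_length x
    mean T fraction over all terminal windows); pass `t_per_read` to
    override.
    """
    rows = []
    if (
        t_per_read is None
        and read_length is not None
        and quants
    ):
        fracs = []
        for iv in reference.intervals:
            q = quants.get(iv.name)
            if q is None:
                continue
            ws, we = reference.terminal_window(iv, window)
            fracs.append(q.t_count / max(we - ws, 1))
        if fracs:
            t_per_read = int(round(read_length * float(np.mean(fracs))))
    for iv in reference.intervals:
        q = quants.get(iv.name)
        if q is None:
            continue
        row = {
            "interval": iv.name,
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "strand": iv.strand,
            "length": iv.length,
            "t_count": q.t_count,
            "n_reads": q.n,
            "tc_reads": q.r_tc,
            "conversion_events": q.n_conversion_events,
            "sum_k": q.sum_k,
            "sum_c": q.sum_c,
        }
        if p_e is not None and p_e > 0:
            est_t = tcontent_fraction(q.k, q.c, p_e)
            row["p_hat_tcontent"] = est_t.value
            row["tcontent_clamped"] = est_t.clamped
            if t_per_read is not None:
                model = ConversionModel(p_e, t_per_read)
                if model.p_tc > 0 and q.n > 0:
                    est_r = read_based_fraction(q.r_tc, q.n, model.p_tc)
                    row["p_hat_read_based"] = est_r.value
                    row["read_based_clamped"] = est_r.clamped
                else:
                    row["p_hat_read_based"] = math.nan
                    row["read_based_clamped"] = False
        rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ planning


def expected_tc_reads(p_su: float, p_e: float, t: int, n: int) -> float:
    """E_SU = p_SU * p_TC * n, the expected number of labeled T>C reads."""
    return p_su * ConversionModel(p_e, t).p_tc * n


def detection_probability(
    p_su: float, p_e: float, t: int, n: int, sensitivity: float,
    model: str = "continuous",
) -> float:
    """Probability of detecting at least one labeled T>C read,
    1 - B(0; E_SU, S).

    E_SU is generally not an integer.  'continuous' evaluates the zero-class
    binomial term with a real exponent, (1 - S)^E_SU — the exact analytic
    continuation; 'ceil' rounds the trial count up (conservative, and badly
    so for E_SU < 1); 'poisson' uses 1 - exp(-E_SU * S), which tracks the
    continuous form closely for small S and undershoots it as S -> 1.
    """
    for name, v in (("p_su", p_su), ("sensitivity", sensitivity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    e_su = expected_tc_reads(p_su, p_e, t, n)
    if model == "poisson":
        return 1.0 - math.exp(-e_su * sensitivity)
    if model == "ceil":
        return 1.0 - (1.0 - sensitivity) ** math.ceil(e_su)
    if sensitivity >= 1.0:
        return 0.0 if e_su == 0 else 1.0
    return 1.0 - (1.0 - sensitivity) ** e_su


def min_coverage(
    p_su: float, p_e: float, t: int, sensitivity: float,
    target_prob: float = 0.95, n_max: int = 10_000_000,
) -> int:
    """Smallest read count n with detection probability >= target_prob."""
    if sensitivity <= 0.0 and target_prob > 0.0:
        raise ValueError("sensitivity 0 can never reach a positive target")
    if p_su <= 0.0 or ConversionModel(p_e, t).p_tc <= 0.0:
        raise ValueError("p_su and p_TC must be positive to reach a target")
    lo, hi = 1, 1
    while detection_probability(p_su, p_e, t, hi, sensitivity) < target_prob:
        hi *= 2
        if hi > n_max:
            raise ValueError(f"no n <= {n_max} reaches target {target_prob}")
    while lo < hi:
        mid = (lo + hi) // 2
        if detection_probability(p_su, p_e, t, mid, sensitivity) >= target_prob:
            hi = mid
        else:
            lo = mid + 1
    return lo


def relative_error(n_true: float, n_detect: float) -> float:
    """E_rel = (N_TRUE - N_DETECT) / N_TRUE; sign preserved."""
    if n_true == 0:
        return math.nan
    return (n_true - n_detect) / n_true
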