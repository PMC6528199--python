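"""End-to-end pipeline: map -> filter/assign -> SNP mask -> quantify.

`run_pipeline` wires the stages together in memory; each stage remains
usable on its own (and via the CLI, with SAM/VCF/TSV as the interchange
formats).  `evaluate_against_truth` scores a pipeline run against the
planted truth of a simulated dataset: per-read labeled/T>C detection,
per-interval assignment correctness and conversion-count recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import MapConfig, ReadMapping, SeedIndex, map_readset
from .filtering import (
    AssignmentResult,
    FilterConfig,
    filter_and_assign,
)
from .genome import ReferenceBundle
from .quantify import IntervalQuant, count_conversions, quant_table, relative_error
from .simulate import SimulatedDataset, parse_read_name
from .variants import SnpMask, VariantCallConfig, call_snps, is_conversion


@dataclass
class PipelineResult:
    mappings: list[ReadMapping]
    assignment: AssignmentResult
    mask: SnpMask
    quants: dict[str, IntervalQuant]
    table: pd.DataFrame
    min_base_quality: int
    conversion_threshold: int

    def read_conversions(self) -> dict[str, int]:
        """Counted (unmasked, quality-passing) T>C conversions per assigned
        read."""
        out = {}
        for r in self.assignment.assigned:
            a = r.alignment
            out[r.name] = sum(
                1
                for mm in a.mismatches
                if is_conversion(mm, a.strand)
                and mm.qual >= self.min_base_quality
                and (a.chrom, mm.gpos) not in self.mask.snps
            )
        return out


def run_pipeline(
    reference: ReferenceBundle,
    reads,
    map_cfg: MapConfig | None = None,
    filter_cfg: FilterConfig | None = None,
    variant_cfg: VariantCallConfig | None = None,
    known_snps: SnpMask | None = None,
    call_variants: bool = True,
    min_base_quality: int = 27,
    conversion_threshold: int = 1,
    p_e: float | None = None,
    read_length: int | None = None,
    index: SeedIndex | None = None,
) -> PipelineResult:
    """Run the full quantification pipeline over a read set."""
    map_cfg = map_cfg or MapConfig()
    filter_cfg = filter_cfg or FilterConfig()
    idx = index or SeedIndex(reference, map_cfg.k)
    mappings = map_readset(reads, idx, map_cfg)
    assignment = filter_and_assign(mappings, reference.intervals, filter_cfg)
    mask = SnpMask()
    if call_variants:
        mask = call_snps(assignment.assigned, reference, variant_cfg)
    if known_snps is not None:
        mask = mask.merge(known_snps)
    quants = count_conversions(
        assignment.assigned, reference, mask, min_base_quality, conversion_threshold
    )
    table = quant_table(quants, reference, p_e=p_e, read_length=read_length)
    return PipelineResult(
        mappings, assignment, mask, quants, table, min_base_quality,
        conversion_threshold,
    )


@dataclass
class TruthEvaluation:
    sensitivity: float  # detected T>C reads among truly labeled reads
    specificity: float  # unlabeled reads not called T>C among all unlabeled
    correct_fraction: float  # reads assigned to their origin interval
    wrong_fraction: float  # reads assigned to a different interval
    per_interval: pd.DataFrame  # truth vs detected conversion counts
    n_reads: int = 0

    @property
    def conversion_count_errors(self) -> pd.Series:
        """Signed per-interval relative error of conversion-count recovery."""
        df = self.per_interval
        ok = df["true_conversions"] > 0
        return (
            (df.loc[ok, "true_conversions"] - df.loc[ok, "detected_conversions"])
            / df.loc[ok, "true_conversions"]
        )


def evaluate_against_truth(
    result: PipelineResult, dataset: SimulatedDataset
) -> TruthEvaluation:
    """Score a pipeline run against the planted truth of its input reads."""
    conv_by_read = result.read_conversions()
    assigned_iv = {r.name: r.interval for r in result.assignment.assigned}
    thr = result.conversion_threshold
    n_lab = n_lab_detected = n_unlab = n_unlab_clean = 0
    n_correct = n_wrong = 0
    true_conv: dict[str, int] = {}
    det_conv: dict[str, int] = {}
    for read in dataset.reads:
        iv, _, labeled, planted = parse_read_name(read.name)
        true_conv[iv] = true_conv.get(iv, 0) + planted
        got = assigned_iv.get(read.name)
        if got is not None:
            if got == iv:
                n_correct += 1
            else:
                n_wrong += 1
        detected = got is not None and conv_by_read.get(read.name, 0) >= thr
        if labeled:
            n_lab += 1
            n_lab_detected += detected
        else:
            n_unlab += 1
            n_unlab_clean += not detected
    for r in result.assignment.assigned:
        det_conv[r.interval] = det_conv.get(r.interval, 0) + conv_by_read.get(r.name, 0)
    names = sorted(true_conv)
    per_interval = pd.DataFrame(
        {
            "true_conversions": [true_conv[n] for n in names],
            "detected_conversions": [det_conv.get(n, 0) for n in names],
        },
        index=pd.Index(names, name="interval"),
    )
    n_total = len(dataset.reads)
    return TruthEvaluation(
        sensitivity=n_lab_detected / n_lab if n_lab else float("nan"),
        specificity=n_unlab_clean / n_unlab if n_unlab else float("nan"),
        correct_fraction=n_correct / n_total if n_total else float("nan"),
        wrong_fraction=n_wrong / n_total if n_total else float("nan"),
        per_interval=per_interval,
        n_reads=n_total,
    )


def fraction_estimate_errors(
    table: pd.DataFrame, truth_p_su: dict[str, float]
) -> pd.DataFrame:
    """Signed relative errors of both labeled-fraction estimators against
    the planted per-interval p_SU (intervals with p_SU = 0 are skipped:
    the relative error is undefined there)."""
    rows = []
    for _, row in table.iterrows():
        p = truth_p_su.get(row["interval"])
        if p is None or p <= 0:
            continue
        entry = {"interval": row["interval"], "p_su": p}
        if "p_hat_tcontent" in row and not np.isnan(row["p_hat_tcontent"]):
            entry["err_tcontent"] = relative_error(p, row["p_hat_tcontent"])
        if "p_hat_read_based" in row and not np.isnan(row.get("p_hat_read_based", np.nan)):
            entry["err_read_based"] = relative_error(p, row["p_hat_read_based"])
        rows.append(entry)
    return pd.DataFrame(rows).set_index("interval")
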