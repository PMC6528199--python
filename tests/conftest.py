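import numpy as np
import pytest

import slamquant as sq


@pytest.fixture(scope="session")
def small_ref():
    """A small synthetic reference: 40 alternating-strand intervals,
    T fraction 0.25, a few planted SNPs."""
    spec = sq.SyntheticGenomeSpec(
        n_intervals=40,
        interval_length=(260, 500),
        t_fraction=0.25,
        duplication_fraction=0.0,
        snp_rate=0.002,
        seed=11,
    )
    return sq.generate_synthetic_reference(spec)


@pytest.fixture(scope="session")
def small_index(small_ref):
    return sq.SeedIndex(small_ref.reference)


@pytest.fixture(scope="session")
def small_dataset(small_ref):
    return sq.simulate_dataset(
        small_ref, p_su=0.5, p_e=0.024, coverage=10, read_length=50, seed=7
    )


@pytest.fixture(scope="session")
def small_run(small_ref, small_index, small_dataset):
    return sq.run_pipeline(
        small_ref.reference,
        small_dataset.reads,
        index=small_index,
        p_e=0.024,
        read_length=50,
    )


def make_alignment(
    chrom="chrS",
    pos=100,
    strand="+",
    read_len=50,
    aligned_len=50,
    mismatches=(),
    score=None,
):
    """Hand-construct an Alignment for unit tests; mismatches are
    (gpos, ref, read, read_pos, qual) tuples with bases as letters."""
    from slamquant.align import Alignment, Mismatch
    from slamquant.genome import BASES

    mms = [
        Mismatch(g, BASES.index(r), BASES.index(q), rp, bq)
        for g, r, q, rp, bq in mismatches
    ]
    n_conv = sum(
        1
        for m in mms
        if (strand == "+" and m.ref == 3 and m.read == 1)
        or (strand == "-" and m.ref == 0 and m.read == 2)
    )
    return Alignment(
        chrom=chrom,
        pos=pos,
        strand=strand,
        score=score if score is not None else 10 * (aligned_len - len(mms)),
        cigar=f"{aligned_len}M" if aligned_len == read_len else f"{aligned_len}M{read_len - aligned_len}S",
        n_matches=aligned_len - len(mms),
        n_conversions=n_conv,
        n_other_mismatches=len(mms) - n_conv,
        aligned_len=aligned_len,
        ref_span=aligned_len,
        read_len=read_len,
        mismatches=mms,
    )
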