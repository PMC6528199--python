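import itertools

import numpy as np
import pytest

import slamquant as sq
from slamquant.genome import T, decode, encode, revcomp
from slamquant.simulate import (
    SimulatedRead,
    make_read_name,
    read_fastq,
    simulate_reads,
    write_fastq,
)


def overlap_oracle(intervals):
    """Brute-force pairwise overlap scan: drop every member of any
    same-strand overlapping pair."""
    drop = set()
    for a, b in itertools.combinations(range(len(intervals)), 2):
        if intervals[a].overlaps(intervals[b]):
            drop.update((a, b))
    return [iv for i, iv in enumerate(intervals) if i not in drop]


class TestDeoverlap:
    def test_disjoint_kept(self):
        ivs = [sq.Interval("c", 0, 10, "a", "+"), sq.Interval("c", 20, 30, "b", "+")]
        assert sq.deoverlap_intervals(ivs) == ivs

    def test_nested_pair_both_removed(self):
        ivs = [sq.Interval("c", 0, 100, "outer", "+"), sq.Interval("c", 10, 20, "inner", "+")]
        assert sq.deoverlap_intervals(ivs) == []

    def test_third_disjoint_interval_survives(self):
        ivs = [
            sq.Interval("c", 0, 50, "a", "+"),
            sq.Interval("c", 40, 90, "b", "+"),
            sq.Interval("c", 200, 250, "cc", "+"),
        ]
        assert [iv.name for iv in sq.deoverlap_intervals(ivs)] == ["cc"]

    def test_opposite_strands_do_not_overlap(self):
        ivs = [sq.Interval("c", 0, 50, "a", "+"), sq.Interval("c", 0, 50, "b", "-")]
        assert sq.deoverlap_intervals(ivs) == ivs

    def test_matches_pairwise_oracle_on_random_sets(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ivs = []
            for i in range(rng.integers(2, 15)):
                start = int(rng.integers(0, 500))
                ivs.append(
                    sq.Interval(
                        "c", start, start + int(rng.integers(1, 80)),
                        f"i{i}", "+" if rng.random() < 0.5 else "-",
                    )
                )
            assert sq.deoverlap_intervals(ivs) == overlap_oracle(ivs)


class TestLabeledFractions:
    def setup_method(self):
        self.ivs = [sq.Interval("c", i * 100, i * 100 + 50, f"i{i}", "+") for i in range(10)]

    def test_fixed(self):
        out = sq.assign_labeled_fractions(self.ivs, "fixed", value=1.0)
        assert set(out.values()) == {1.0}
        half = sq.assign_labeled_fractions(self.ivs, "fixed", value=0.5)
        assert all(v == 0.5 for v in half.values()) and len(half) == 10

    def test_fixed_requires_valid_value(self):
        with pytest.raises(ValueError):
            sq.assign_labeled_fractions(self.ivs, "fixed", value=1.5)

    def test_uniform_mean_and_determinism(self):
        ivs = [sq.Interval("c", i, i + 1, f"i{i}", "+") for i in range(10_000)]
        out = sq.assign_labeled_fractions(ivs, "uniform", rng=5)
        vals = np.array(list(out.values()))
        se = 1 / np.sqrt(12 * len(vals))
        assert abs(vals.mean() - 0.5) < 3 * se
        again = sq.assign_labeled_fractions(ivs, "uniform", rng=5)
        assert out == again

    def test_table_missing_interval(self):
        with pytest.raises(KeyError, match="i3"):
            sq.assign_labeled_fractions(
                self.ivs, "table", table={f"i{i}": 0.1 for i in range(3)}
            )


class TestPlantSnps:
    def test_rate_zero_identity(self):
        seq = encode("ACGTACGT")
        out, snps = sq.plant_snps(seq, 0.0, np.random.default_rng(0))
        assert np.array_equal(out, seq) and snps == []

    def test_rate_one_forces_mutation(self):
        out, snps = sq.plant_snps(encode("AAAA"), 1.0, np.random.default_rng(1))
        assert not np.any(out == 0) and len(snps) == 4

    def test_n_positions_skipped(self):
        out, snps = sq.plant_snps(encode("NNNN"), 1.0, np.random.default_rng(1))
        assert decode(out) == "NNNN" and snps == []

    def test_rate_matches_binomial(self):
        n = 1_000_000
        rng = np.random.default_rng(2)
        seq = rng.integers(0, 4, n).astype(np.uint8)
        _, snps = sq.plant_snps(seq, 0.001, rng)
        sd = np.sqrt(n * 0.001 * 0.999)
        assert abs(len(snps) - 1000) < 4 * sd


class TestSimulateReads:
    def test_psu_zero_no_labels(self):
        win = encode("ACGT" * 100)
        reads, n = simulate_reads(win, 0.0, 0.07, 5, 50, rng=0)
        assert n == len(reads)
        assert all(not lab and k == 0 for _, _, lab, k, _ in reads)

    def test_pe_zero_all_labeled_zero_conversions(self):
        win = encode("ACGT" * 100)
        reads, _ = simulate_reads(win, 1.0, 0.0, 5, 50, rng=0)
        assert all(lab and k == 0 for _, _, lab, k, _ in reads)

    def test_read_too_long_rejected(self):
        with pytest.raises(ValueError, match="read length"):
            simulate_reads(encode("ACGT" * 10), 0.5, 0.02, 5, 100, rng=0)

    def test_conversion_fraction_matches_closed_form(self):
        # reads with exactly t=11 Ts: fraction with >=1 conversion should be
        # 1 - (1 - p_e)^11, about 23.5% at p_e = 0.024
        rng = np.random.default_rng(9)
        base = "ACG" * 13  # T-free filler, length 39
        win = encode(("T" * 11) + base)  # every full-window read has t=11
        p = 1 - (1 - 0.024) ** 11
        reads, n = simulate_reads(win, 1.0, 0.024, 1000, 50, error_rate=0.0, rng=rng)
        frac = np.mean([k >= 1 for _, _, _, k, _ in reads])
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 4 * se

    def test_mean_conversions_matches_binomial_model(self):
        rng = np.random.default_rng(10)
        win = encode("T" * 20 + "ACG" * 10)
        p_e = 0.07
        reads, n = simulate_reads(win, 1.0, p_e, 1500, 50, error_rate=0.0, rng=rng)
        ks = np.array([k for _, _, _, k, _ in reads])
        t = 20
        se = np.sqrt(t * p_e * (1 - p_e) / n)
        assert abs(ks.mean() - t * p_e) < 3 * se

    def test_forced_conversion_mode(self):
        rng = np.random.default_rng(11)
        win = encode("TACG" * 18)  # Ts present in every 50-bp read
        reads, _ = simulate_reads(win, 1.0, 0.024, 200, 50, rng=rng, min_conversions=1)
        assert all(k >= 1 for _, _, lab, k, _ in reads if lab)

    def test_bad_cycles_get_low_quality(self):
        win = encode("ACGT" * 30)
        reads, _ = simulate_reads(win, 0.0, 0.0, 2, 50, rng=0, bad_cycles=[7])
        for _, qual, *_ in reads:
            assert qual[7] == 10 and qual[6] == 30


class TestDataset:
    def test_truth_count_conservation(self, small_ref, small_dataset):
        truth = small_dataset.truth
        assert truth["n_reads"].sum() == len(small_dataset.reads)
        per_iv = {}
        n_lab = {}
        for r in small_dataset.reads:
            iv, _, lab, k = sq.parse_read_name(r.name)
            per_iv[iv] = per_iv.get(iv, 0) + 1
            n_lab[iv] = n_lab.get(iv, 0) + lab
        for _, row in truth.iterrows():
            assert per_iv[row["interval"]] == row["n_reads"]
            assert n_lab[row["interval"]] == row["n_labeled_reads"]

    def test_read_names_encode_truth(self, small_dataset):
        r = small_dataset.reads[0]
        iv, idx, lab, k = sq.parse_read_name(r.name)
        assert iv == r.interval and lab == r.labeled and k == r.n_conversions

    def test_reads_come_from_terminal_window(self, small_ref):
        ds = sq.simulate_dataset(small_ref, 1.0, 0.0, coverage=3, read_length=50,
                                 error_rate=0.0, seed=3)
        bundle = small_ref.reference
        for r in ds.reads[:200]:
            iv = bundle.interval(r.interval)
            ws, we = bundle.terminal_window(iv, 250)
            assert ws <= r.gstart and r.gstart + 50 <= we
            # the read must equal the sample genome slice in transcript orientation
            gslice = small_ref.sample_sequences[r.chrom][r.gstart : r.gstart + 50]
            expect = revcomp(gslice) if r.strand == "-" else gslice
            assert np.array_equal(r.seq, expect)

    def test_seed_determinism_byte_identical(self, tmp_path):
        spec = sq.SyntheticGenomeSpec(n_intervals=5, interval_length=(260, 300), seed=4)
        files = []
        for run in ("a", "b"):
            ref = sq.generate_synthetic_reference(spec)
            ds = sq.simulate_dataset(ref, 0.5, 0.024, coverage=3, read_length=50, seed=8)
            fa, bed, vcf, fq = (tmp_path / f"{run}.{ext}" for ext in ("fa", "bed", "vcf", "fq"))
            ref.write(fa, bed, vcf)
            ds.write_fastq(fq)
            files.append((fa.read_bytes(), bed.read_bytes(), vcf.read_bytes(), fq.read_bytes()))
        assert files[0] == files[1]


class TestSyntheticReference:
    def test_no_duplication_means_unique_13mers(self):
        spec = sq.SyntheticGenomeSpec(
            n_intervals=8, interval_length=(260, 400), duplication_fraction=0.0,
            snp_rate=0.0, seed=21,
        )
        ref = sq.generate_synthetic_reference(spec)
        genome = decode(ref.reference.sequences["chrS"])
        k = 13
        counts = {}
        for i in range(len(genome) - k + 1):
            km = genome[i : i + k]
            counts[km] = counts.get(km, 0) + 1
        for iv in ref.reference.intervals:
            sub = genome[iv.start : iv.end]
            dup = [counts[sub[i : i + k]] for i in range(len(sub) - k + 1)]
            assert np.mean(np.array(dup) > 1) < 0.02  # rare chance collisions only

    def test_duplicates_share_high_identity(self):
        spec = sq.SyntheticGenomeSpec(
            n_intervals=10, interval_length=(300, 400), duplication_fraction=0.4,
            snp_rate=0.0, seed=22,
        )
        ref = sq.generate_synthetic_reference(spec)
        assert ref.duplicated_outside  # some copies land outside the annotation

    def test_t_fraction_zero_plants_no_conversions(self):
        spec = sq.SyntheticGenomeSpec(
            n_intervals=4, interval_length=(260, 300), t_fraction=0.0,
            snp_rate=0.0, seed=23,
        )
        ref = sq.generate_synthetic_reference(spec)
        ds = sq.simulate_dataset(ref, 1.0, 0.5, coverage=3, read_length=50, seed=1)
        assert all(r.n_conversions == 0 for r in ds.reads)

    def test_genome_size_cap(self):
        with pytest.raises(ValueError, match="cap"):
            sq.SyntheticGenomeSpec(n_intervals=10**6, interval_length=(250, 4000))

    def test_fastq_roundtrip(self, tmp_path, small_dataset):
        path = tmp_path / "r.fq"
        write_fastq(path, small_dataset.reads[:10])
        back = read_fastq(path)
        for r, (name, seq, qual) in zip(small_dataset.reads[:10], back):
            assert name == r.name
            assert np.array_equal(seq, r.seq)
            assert np.array_equal(qual, r.qual)
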