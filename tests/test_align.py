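import numpy as np
import pytest

import slamquant as sq
from slamquant.align import MapConfig, SeedIndex, _affine_sw, _local_trim, find_cmrs
from slamquant.genome import Interval, ReferenceBundle, decode, encode, revcomp
from slamquant.scoring import ScoringScheme


def make_reference(seq: str, name="chr1", intervals=()):
    return ReferenceBundle({name: encode(seq)}, list(intervals))


@pytest.fixture(scope="module")
def toy_ref():
    rng = np.random.default_rng(42)
    genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
    return make_reference(genome)


@pytest.fixture(scope="module")
def toy_index(toy_ref):
    return SeedIndex(toy_ref)


def read_at(ref, start, length, chrom="chr1"):
    return ref.sequences[chrom][start : start + length].copy()


def kmer_hit_oracle(genome: str, kmer: str) -> set[int]:
    """Exhaustive scan: positions whose genome 13-mer equals the read k-mer
    allowing only reference-T/read-C differences."""
    out = set()
    k = len(kmer)
    for i in range(len(genome) - k + 1):
        ref = genome[i : i + k]
        if all(r == q or (r == "T" and q == "C") for r, q in zip(ref, kmer)):
            out.add(i)
    return out


class TestSeeding:
    def test_exact_unique_read_gives_one_cmr(self, toy_ref, toy_index):
        query = read_at(toy_ref, 500, 50)
        cmrs = find_cmrs(query, toy_index, "+")
        assert len(cmrs) == 1
        assert cmrs[0].diagonal == 500

    def test_conversion_in_every_seed_still_found(self, toy_ref, toy_index):
        # plant a T>C conversion every ~10 bp so every 13-mer contains one
        query = read_at(toy_ref, 800, 60)
        tpos = np.flatnonzero(query == 3)
        chosen = tpos[::3][:8]
        assert len(chosen) >= 5
        query[chosen] = 1  # T -> C
        cmrs = find_cmrs(query, toy_index, "+")
        assert any(c.diagonal == 800 for c in cmrs)

    def test_seed_hits_match_exhaustive_oracle(self, toy_ref, toy_index):
        genome = decode(toy_ref.sequences["chr1"])
        rng = np.random.default_rng(1)
        for start in (100, 700, 1500):
            query = read_at(toy_ref, start, 13)
            tpos = np.flatnonzero(query == 3)
            if tpos.size:
                query[rng.choice(tpos)] = 1
            gpos, qoff = toy_index.seed_hits(query, "+", True)
            assert set(int(p) for p in gpos) == kmer_hit_oracle(genome, decode(query))

    def test_absent_sequence_gives_no_cmrs(self, toy_index):
        rng = np.random.default_rng(7)
        # random 50-mer is essentially never present in a 3-kb genome
        query = rng.integers(0, 4, 50).astype(np.uint8)
        gpos, _ = toy_index.seed_hits(query, "+", True)
        spurious = find_cmrs(query, toy_index, "+") if gpos.size else []
        assert all(c.seed_count <= 2 for c in spurious)

    def test_standard_mode_requires_exact_seeds(self, toy_ref, toy_index):
        query = read_at(toy_ref, 800, 26)
        tpos = np.flatnonzero(query == 3)
        query[tpos] = 1
        aware_hits, _ = toy_index.seed_hits(query, "+", True)
        strict_hits, _ = toy_index.seed_hits(query, "+", False)
        assert len(strict_hits) < len(aware_hits)


class TestAlignScores:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        self.ref = make_reference(self.genome)
        self.index = SeedIndex(self.ref)
        self.cfg = MapConfig()

    def _best(self, query):
        m = sq.map_readset([("r", query, np.full(len(query), 30, dtype=np.int16))],
                           self.index, self.cfg)[0]
        assert m.status == "mapped"
        return m.best

    def test_perfect_20bp_read_scores_200(self):
        query = self.ref.sequences["chr1"][100:120].copy()
        assert self._best(query).score == 200

    def test_one_conversion_scores_190(self):
        query = self.ref.sequences["chr1"][100:120].copy()
        tpos = np.flatnonzero(query == 3)
        query[tpos[len(tpos) // 2]] = 1
        a = self._best(query)
        assert a.score == 190 and a.n_conversions == 1

    def test_one_ordinary_mismatch_scores_185(self):
        # mismatch near the read start: an intact 13-mer seed remains and
        # local trimming keeps the flanking matches (3x10 - 15 > 0)
        query = self.ref.sequences["chr1"][100:120].copy()
        apos = np.flatnonzero(query[13:18] == 0) + 13
        assert apos.size, "fixture genome lacks an A in positions 13..17"
        query[apos[0]] = 2  # A -> G on the plus strand: plain mismatch
        a = self._best(query)
        # 19 matches + one -15 mismatch: 19 * 10 - 15
        assert a.score == 175 and a.n_other_mismatches == 1 and a.aligned_len == 20

    def test_score_oracle_column_by_column(self, small_ref, small_index, small_dataset):
        """Recomputing each emitted score from its alignment columns with
        score_pair reproduces the stored score exactly (gapless records)."""
        scheme = ScoringScheme()
        mapped = sq.map_readset(small_dataset.reads[:300], small_index, MapConfig())
        checked = 0
        for m in mapped:
            for a in m.alignments:
                if "I" in a.cigar or "D" in a.cigar:
                    continue
                expected = (
                    a.n_matches * scheme.match_score
                    + a.n_conversions * scheme.effective_tc_score
                    + a.n_other_mismatches * scheme.mismatch_score
                )
                assert a.score == expected
                checked += 1
        assert checked > 100


class TestReverseStrand:
    def test_minus_strand_read_maps_with_conversion(self):
        rng = np.random.default_rng(8)
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
        ref = make_reference(genome)
        index = SeedIndex(ref)
        gslice = ref.sequences["chr1"][200:260]
        transcript = revcomp(gslice)  # read in transcript orientation
        tpos = np.flatnonzero(transcript == 3)
        transcript = transcript.copy()
        transcript[tpos[0]] = 1  # one T>C conversion in transcript space
        m = sq.map_readset(
            [("r", transcript, np.full(60, 30, dtype=np.int16))], index, MapConfig()
        )[0]
        a = m.best
        assert a is not None and a.strand == "-" and a.pos == 200
        assert a.n_conversions == 1 and a.n_other_mismatches == 0
        # in genome-forward coordinates the event is reference A -> read G
        mm = a.mismatches[0]
        assert (mm.ref, mm.read) == (0, 2)


class TestSmithWatermanFallback:
    def test_deletion_in_read_recovered(self):
        rng = np.random.default_rng(9)
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        ref = make_reference(genome)
        index = SeedIndex(ref)
        # read = reference 100..160 with 2 bases deleted in the middle
        block = decode(ref.sequences["chr1"][100:160])
        query = encode(block[:30] + block[32:])
        m = sq.map_readset([("r", query, np.full(58, 30, dtype=np.int16))],
                           index, MapConfig())[0]
        a = m.best
        assert a is not None and "D" in a.cigar
        # affine gap: 58 matches + open/extend for a 2-bp deletion
        assert a.score == 58 * 10 - 20 - 5 * 2

    def test_affine_sw_simple_case(self):
        scheme = ScoringScheme()
        q = encode("ACGTACGT")
        r = encode("ACGTTACGT")  # one-base insertion in the reference
        score, qs, qe, rs, re_, ops = _affine_sw(q, r, scheme.matrix("+"),
                                                 scheme.gap_open, scheme.gap_extend)
        assert score == 80 - 25
        assert [op for op, _ in ops] == ["M", "D", "M"]


class TestLocalTrim:
    def test_prefers_longest_on_ties(self):
        # zero-scoring conversion columns at the edges are kept
        s = np.array([0, 10, 10, 0])
        assert _local_trim(s) == (0, 4, 20)

    def test_trims_negative_edges(self):
        s = np.array([-15, 10, 10, -15])
        assert _local_trim(s) == (1, 3, 20)

    def test_all_negative_empty(self):
        assert _local_trim(np.array([-15, -15]))[2] == 0


class TestMapReadset:
    def test_empty_input_gives_empty_sam(self, toy_ref, tmp_path):
        mappings = sq.map_readset([], toy_ref)
        path = tmp_path / "empty.sam"
        sq.mappings_to_sam(mappings, toy_ref, path)
        import pysam

        with pysam.AlignmentFile(path, check_sq=False) as fh:
            assert fh.header.nreferences == 1
            assert list(fh) == []

    def test_read_shorter_than_k_unmapped(self, toy_index):
        m = sq.map_readset([("tiny", encode("ACGT"), np.full(4, 30, dtype=np.int16))],
                           toy_index)[0]
        assert m.status == "unmapped"

    def test_simulated_reads_map_to_origin(self, small_ref, small_index):
        ds = sq.simulate_dataset(small_ref, 0.0, 0.0, coverage=3, read_length=50,
                                 error_rate=0.0, seed=5)
        mapped = sq.map_readset(ds.reads, small_index)
        ok = 0
        for r, m in zip(ds.reads, mapped):
            a = m.best
            ok += (
                a is not None
                and a.chrom == r.chrom
                and a.strand == r.strand
                and abs(a.pos - r.gstart) <= 2
            )
        assert ok / len(ds.reads) >= 0.99

    def test_mapping_is_deterministic(self, small_ref, small_index, small_dataset):
        a = sq.map_readset(small_dataset.reads[:100], small_index)
        b = sq.map_readset(small_dataset.reads[:100], small_index)
        assert [(m.status, [(x.chrom, x.pos, x.score) for x in m.alignments]) for m in a] \
            == [(m.status, [(x.chrom, x.pos, x.score) for x in m.alignments]) for m in b]

    def test_sam_roundtrip(self, small_ref, small_index, small_dataset, tmp_path):
        mappings = sq.map_readset(small_dataset.reads[:50], small_index)
        path = tmp_path / "out.sam"
        sq.mappings_to_sam(mappings, small_ref.reference, path)
        back = sq.sam_to_mappings(path)
        assert len(back) == len(mappings)
        for m, b in zip(mappings, back):
            assert m.name == b.name and m.status == b.status
            for x, y in zip(m.alignments, b.alignments):
                assert (x.chrom, x.pos, x.strand, x.score, x.cigar) == (
                    y.chrom, y.pos, y.strand, y.score, y.cigar,
                )
                assert [(mm.gpos, mm.ref, mm.read, mm.read_pos, mm.qual)
                        for mm in x.mismatches] == [
                    (mm.gpos, mm.ref, mm.read, mm.read_pos, mm.qual)
                    for mm in y.mismatches
                ]

    def test_multimapper_gets_two_locations(self):
        rng = np.random.default_rng(12)
        unit = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        spacer = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        genome = unit + spacer + unit  # exact duplicate
        ref = make_reference(genome)
        index = SeedIndex(ref)
        query = encode(unit[50:110])
        m = sq.map_readset([("r", query, np.full(60, 30, dtype=np.int16))],
                           index, MapConfig())[0]
        assert m.status == "mapped"
        assert len(m.alignments) == 2
        assert m.best.n_locations == 2
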