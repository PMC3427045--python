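"""Alignment oracle checks and W/T/O duplication typing."""

import pytest

from ccchzf.alignment import needleman_wunsch, smith_waterman
from ccchzf.duplication import (
    ParalogPair,
    assign_duplication_type,
    is_tandem,
    summarize_duplication,
)
from ccchzf.io_formats import DuplicatedBlock, GeneLocus
from oracles import ToyMatrix, enumerate_global, enumerate_local

import numpy as np

TOY = ToyMatrix(match=5.0, mismatch=-4.0)
GAPS = dict(gap_open=4.0, gap_extend=1.0)


def _random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestSmithWaterman:
    def test_self_alignment_full_identity(self):
        res = smith_waterman("MKVLAW", "MKVLAW")
        assert res.identity_pct == 100.0
        assert res.aligned_a == res.aligned_b == "MKVLAW"

    def test_score_matches_enumeration_small(self):
        res = smith_waterman("MKV", "MRV")
        from ccchzf.alignment import blosum62
        assert res.score == enumerate_global("MKV", "MRV", blosum62(), 10, 0.5)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            smith_waterman("", "MK")

    @pytest.mark.parametrize("seed", range(8))
    def test_local_score_equals_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(400 + seed)
        a = _random_dna(rng, int(rng.integers(2, 6)))
        b = _random_dna(rng, int(rng.integers(2, 6)))
        got = smith_waterman(a, b, TOY, **GAPS).score
        assert got == pytest.approx(enumerate_local(a, b, TOY, **GAPS))

    def test_exhaustive_over_all_short_pairs(self):
        """Every pair of length <= 2 over {A,C,G,T} matches the oracle."""
        pool = [x + y for x in "ACGT" for y in "ACGT"] + list("ACGT")
        for a in pool:
            for b in pool:
                got = smith_waterman(a, b, TOY, **GAPS).score
                assert got == pytest.approx(enumerate_local(a, b, TOY, **GAPS))

    def test_mutated_pair_similarity_bounds(self, rng):
        """~85 % conserved 200-mers align with identity >= 80 %."""
        aa = "ACDEFGHIKLMNPQRSTVWY"
        base = "".join(aa[i] for i in rng.integers(0, 20, 200))
        mutated = list(base)
        sites = rng.choice(200, size=30, replace=False)
        for s in sites:
            mutated[s] = aa[int(rng.integers(0, 20))]
        res = smith_waterman(base, "".join(mutated))
        assert res.similarity_pct >= res.identity_pct >= 80.0
        assert res.identity_pct <= res.similarity_pct <= 100.0

    def test_determinism(self, rng):
        a = _random_dna(rng, 50)
        b = _random_dna(rng, 50)
        r1 = smith_waterman(a, b, TOY, **GAPS)
        r2 = smith_waterman(a, b, TOY, **GAPS)
        assert r1 == r2


class TestNeedlemanWunsch:
    def test_identical_no_gaps(self):
        res = needleman_wunsch("MKVLAW", "MKVLAW")
        assert res.identity_pct == 100.0 and "-" not in res.aligned_a

    def test_length_forced_terminal_gap(self):
        res = needleman_wunsch("MK", "M")
        assert res.aligned_a == "MK" and res.aligned_b == "M-"

    @pytest.mark.parametrize("seed", range(8))
    def test_global_score_equals_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(500 + seed)
        a = _random_dna(rng, int(rng.integers(1, 6)))
        b = _random_dna(rng, int(rng.integers(1, 6)))
        got = needleman_wunsch(a, b, TOY, **GAPS).score
        assert got == pytest.approx(enumerate_global(a, b, TOY, **GAPS))


def _locus(gene, chrom, start, end, idx):
    return GeneLocus(gene, chrom, start, end, "+", idx)


class TestTandemRule:
    def test_all_criteria_met(self):
        a = _locus("a", "chr1", 1_000, 2_000, 10)
        b = _locus("b", "chr1", 50_001, 51_000, 13)  # 48 kb gap
        ok, ev = is_tandem(a, b, 85.0)
        assert ok and ev.intervening_loci == 2 and ev.distance_bp == 48_000

    def test_locus_criterion_fails(self):
        a = _locus("a", "chr1", 1_000, 2_000, 10)
        b = _locus("b", "chr1", 50_001, 51_000, 17)  # 6 intervening
        assert not is_tandem(a, b, 85.0)[0]

    def test_distance_criterion_fails(self):
        a = _locus("a", "chr1", 1_000, 2_000, 10)
        b = _locus("b", "chr1", 152_002, 153_000, 12)  # 150 kb gap
        assert not is_tandem(a, b, 85.0)[0]

    def test_similarity_criterion_fails(self):
        a = _locus("a", "chr1", 1_000, 2_000, 10)
        b = _locus("b", "chr1", 30_000, 31_000, 11)
        assert not is_tandem(a, b, 79.9)[0]

    def test_different_chromosome_is_negative_not_error(self):
        a = _locus("a", "chr1", 1_000, 2_000, 1)
        b = _locus("b", "chr2", 1_000, 2_000, 1)
        ok, ev = is_tandem(a, b, 99.0)
        assert not ok and ev.note == "different_chromosome"

    def test_symmetry(self):
        a = _locus("a", "chr1", 1_000, 2_000, 10)
        b = _locus("b", "chr1", 50_001, 51_000, 13)
        assert is_tandem(a, b, 85.0)[0] == is_tandem(b, a, 85.0)[0]

    def test_overlapping_intervals_distance_zero(self):
        a = _locus("a", "chr1", 1_000, 5_000, 1)
        b = _locus("b", "chr1", 4_000, 9_000, 2)
        assert is_tandem(a, b, 90.0)[1].distance_bp == 0


class TestAssignType:
    @pytest.fixture
    def setup(self):
        loci = {
            "w1": _locus("w1", "chr1", 10_000, 12_000, 3),
            "w2": _locus("w2", "chr2", 20_000, 22_000, 4),
            "t1": _locus("t1", "chr3", 1_000, 2_000, 1),
            "t2": _locus("t2", "chr3", 30_000, 31_000, 2),
            "o1": _locus("o1", "chr1", 500_000, 502_000, 9),
            "o2": _locus("o2", "chr4", 500_000, 502_000, 9),
        }
        blocks = [DuplicatedBlock("B7", ("chr1", 5_000, 50_000),
                                  ("chr2", 15_000, 60_000))]
        return loci, blocks

    def test_block_containment_gives_w(self, setup):
        loci, blocks = setup
        pair = assign_duplication_type("w1", "w2", loci, blocks, 90.0)
        assert pair.duplication_type == "W" and pair.block_pair_id == "B7"

    def test_tandem_without_block_gives_t(self, setup):
        loci, blocks = setup
        assert assign_duplication_type(
            "t1", "t2", loci, blocks, 90.0
        ).duplication_type == "T"

    def test_cross_chromosome_gives_o(self, setup):
        loci, blocks = setup
        assert assign_duplication_type(
            "o1", "o2", loci, blocks, 90.0
        ).duplication_type == "O"

    def test_missing_gene_names_it(self, setup):
        loci, blocks = setup
        with pytest.raises(KeyError, match="ghost"):
            assign_duplication_type("w1", "ghost", loci, blocks, 90.0)

    def test_types_exclusive_and_exhaustive(self, setup):
        loci, blocks = setup
        for g1, g2 in (("w1", "w2"), ("t1", "t2"), ("o1", "o2")):
            t = assign_duplication_type(g1, g2, loci, blocks, 90.0)
            assert t.duplication_type in ("W", "T", "O")


class TestSummary:
    def test_single_pair(self):
        s = summarize_duplication([ParalogPair("a", "b", "T")])
        assert s["counts"] == {"W": 0, "T": 1, "O": 0}
        assert s["percentages"]["T"] == 100.0

    def test_counts_sum(self):
        pairs = (
            [ParalogPair(f"a{i}", f"b{i}", "W") for i in range(10)]
            + [ParalogPair(f"c{i}", f"d{i}", "T") for i in range(3)]
            + [ParalogPair(f"e{i}", f"f{i}", "O") for i in range(2)]
        )
        s = summarize_duplication(pairs)
        assert s["counts"] == {"W": 10, "T": 3, "O": 2}
        assert sum(s["counts"].values()) == s["total"] == 15
        assert s["percentages"]["W"] == 66.7
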