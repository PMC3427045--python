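"""Generator determinism and truth-consistency with the analysis operations."""

import numpy as np
import pytest

from ccchzf.duplication import assign_duplication_type, summarize_duplication
from ccchzf.kaks import kaks_for_cds_pair
from ccchzf.motif_scan import ScanConfig, scan_ccch
from ccchzf.protein_features import detect_tzf, find_nes
from ccchzf import synthetic_data as sd


class TestProteome:
    def test_determinism_byte_identical(self):
        r1, t1 = sd.gen_proteome(10, nes_rate=0.5, tzf_rate=0.3, seed=42)
        r2, t2 = sd.gen_proteome(10, nes_rate=0.5, tzf_rate=0.3, seed=42)
        assert [(r.id, r.sequence) for r in r1] == [
            (r.id, r.sequence) for r in r2
        ]
        assert t1 == t2

    def test_single_planted_motif_recovered(self):
        records, truths = sd.gen_proteome(
            1, motif_spec=[((7, 5, 3), (1, 1))], length_range=(60, 60), seed=7
        )
        ann = scan_ccch(records[0].sequence)
        assert [(m.start, m.spacing) for m in ann.motifs] == [
            (p.start, p.spacing) for p in truths[0].motifs
        ]

    def test_planted_motif_recall_and_precision(self):
        """Recall and precision both 1.0 against generator truth."""
        records, truths = sd.gen_proteome(
            40,
            motif_spec=[((7, 5, 3), (0, 2)), ((8, 5, 3), (0, 2)),
                        ((11, 6, 3), (0, 1))],
            seed=13,
        )
        for rec, truth in zip(records, truths):
            found = {(m.start, m.spacing) for m in scan_ccch(rec.sequence).motifs}
            planted = {(p.start, p.spacing) for p in truth.motifs}
            assert found == planted

    def test_nes_rate_zero_means_no_nes(self):
        records, _ = sd.gen_proteome(20, nes_rate=0.0, seed=3)
        assert all(not find_nes(r.sequence) for r in records)

    def test_nes_planted_recall(self):
        records, truths = sd.gen_proteome(30, nes_rate=1.0, seed=5)
        for rec, truth in zip(records, truths):
            starts = {m.start for m in find_nes(rec.sequence)}
            assert set(truth.nes_starts) <= starts

    def test_tzf_rate_one_all_tzf(self):
        records, truths = sd.gen_proteome(10, tzf_rate=1.0, seed=8)
        for rec, truth in zip(records, truths):
            assert truth.is_tzf
            ann = scan_ccch(rec.sequence)
            assert detect_tzf(ann, rec.sequence).is_tzf

    def test_infeasible_packing_errors(self):
        with pytest.raises(ValueError, match="exceed"):
            sd.gen_proteome(1, motif_spec=[((8, 5, 3), (5, 5))],
                            length_range=(40, 40), seed=1)

    def test_hard_mode_truth_via_exhaustive_scan(self):
        """Full-alphabet background: planted motifs are still among the
        exhaustive matches even if chance matches appear."""
        records, truths = sd.gen_proteome(
            10, motif_spec=[((8, 5, 3), (1, 1))], seed=21, hard_mode=True
        )
        config = ScanConfig(overlap_policy="all_matches")
        for rec, truth in zip(records, truths):
            found = {(m.start, m.spacing)
                     for m in scan_ccch(rec.sequence, config).motifs}
            assert {(p.start, p.spacing) for p in truth.motifs} <= found


class TestGeneMap:
    def test_planted_types_recovered(self):
        truth = sd.gen_gene_map(n_chrom=4, genes_per_chrom=20,
                                n_tandem_arrays=3, n_block_pairs=4,
                                n_other_pairs=2, seed=17)
        loci = {l.gene_id: l for l in truth.loci}
        typed = [
            assign_duplication_type(g1, g2, loci, truth.blocks, 90.0)
            for g1, g2, _ in truth.pairs
        ]
        got = [p.duplication_type for p in typed]
        assert got == [t for _, _, t in truth.pairs]
        summary = summarize_duplication(typed)
        assert summary["counts"] == {"W": 8, "T": 3, "O": 2}

    def test_no_blocks_never_w(self):
        truth = sd.gen_gene_map(n_block_pairs=0, seed=4)
        loci = {l.gene_id: l for l in truth.loci}
        for g1, g2, _ in truth.pairs:
            pair = assign_duplication_type(g1, g2, loci, [], 90.0)
            assert pair.duplication_type != "W"

    def test_locus_invariants(self):
        truth = sd.gen_gene_map(seed=2)
        by_chrom = {}
        for l in truth.loci:
            by_chrom.setdefault(l.chrom_label, []).append(l)
        for group in by_chrom.values():
            group.sort(key=lambda l: l.locus_index)
            for a, b in zip(group, group[1:]):
                assert a.end < b.start  # non-overlapping
                assert b.locus_index == a.locus_index + 1


class TestCdsPairs:
    def test_determinism(self):
        p1, t1 = sd.gen_cds_pairs(5, n_codons=60, omega=0.3, seed=31)
        p2, t2 = sd.gen_cds_pairs(5, n_codons=60, omega=0.3, seed=31)
        assert [(a.sequence, b.sequence) for a, b in p1] == [
            (a.sequence, b.sequence) for a, b in p2
        ]
        assert t1 == t2

    def test_omega_zero_forces_pure_synonymous(self):
        """omega = 0 admits only synonymous events; the NG86 Ka estimate is
        near (not exactly) zero because two synonymous hits landing in one
        codon are pathway-averaged over orderings whose alternative order
        can pass through a different amino acid."""
        pairs, truths = sd.gen_cds_pairs(5, n_codons=100, omega=0.0,
                                         expected_sub_per_codon=0.2, seed=19)
        for (a, b), truth in zip(pairs, truths):
            assert truth.n_nonsyn_events == 0
            res = kaks_for_cds_pair(a.sequence, b.sequence)
            assert res.Ka <= 0.01

    def test_zero_divergence_identical_pair(self):
        pairs, _ = sd.gen_cds_pairs(3, n_codons=50, omega=0.3,
                                    expected_sub_per_codon=0.0, seed=23)
        for a, b in pairs:
            assert a.sequence == b.sequence
            res = kaks_for_cds_pair(a.sequence, b.sequence)
            assert res.Ks == res.Ka == 0.0

    def test_no_stop_codons_emitted(self):
        from ccchzf.kaks import GENETIC_CODE

        pairs, _ = sd.gen_cds_pairs(5, n_codons=80, omega=1.0, seed=37)
        for a, b in pairs:
            for seq in (a.sequence, b.sequence):
                codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
                assert all(GENETIC_CODE[c] != "*" for c in codons)


class TestExpressionGen:
    def test_determinism(self):
        v1, g1, l1, t1 = sd.gen_expression([1, 2, 3, 4], noise_sd=0.1, seed=9)
        v2, g2, l2, t2 = sd.gen_expression([1, 2, 3, 4], noise_sd=0.1, seed=9)
        assert np.array_equal(v1, v2) and g1 == g2 and t1 == t2

    def test_noise_free_categories_exact(self):
        import pandas as pd

        from ccchzf.expression import (
            ExpressionMatrix, categorize_pair, expressed_sets,
            genewise_normalize,
        )

        values, genes, labels, truths = sd.gen_expression(
            [1, 2, 3, 4] * 5, noise_sd=0.0, seed=41
        )
        em = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=labels))
        sets = expressed_sets(genewise_normalize(em))
        for t in truths:
            assert sets[t.gene1] == t.set1
            assert sets[t.gene2] == t.set2
            assert categorize_pair(sets[t.gene1], sets[t.gene2]).category == t.category
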