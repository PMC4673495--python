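"""Block filtering, NG86 counting, the PSG screen, and expression overlap."""

import math

import numpy as np
import pandas as pd
import pytest

from gekkota.selection import (
    GENETIC_CODE, SENSE_CODONS, STOP_CODONS, CodonAlignment,
    EmptyAlignmentError, expression_overlap, filter_blocks, ng86_kaks,
    ng86_sites, screen_psg,
)
from gekkota.simulate import CodonSimConfig, simulate_codon_pair


def brute_force_filter(aln, min_cons, max_gap, min_block):
    """Independent column-wise reimplementation of the block filter."""
    n = len(aln.seqs)
    cols = []
    for k in range(aln.n_codons):
        col = [s[3 * k: 3 * k + 3] for s in aln.seqs]
        gap_frac = sum("-" in c for c in col) / n
        ungapped = [c for c in col if "-" not in c]
        if gap_frac > max_gap or not ungapped:
            cols.append(False)
            continue
        modal = max(ungapped.count(c) for c in ungapped)
        cols.append(modal / len(ungapped) >= min_cons)
    keep = []
    k = 0
    while k < len(cols):
        if cols[k]:
            j = k
            while j < len(cols) and cols[j]:
                j += 1
            if j - k >= min_block:
                keep.extend(range(k, j))
            k = j
        else:
            k += 1
    return keep


class TestFilterBlocks:
    def test_identical_gapfree_pair_unchanged(self):
        aln = CodonAlignment(("a", "b"), ("ATGAAACCC", "ATGAAACCC"))
        assert filter_blocks(aln, 0.5, 0.2, 1).seqs == aln.seqs

    def test_gapped_column_removed_at_zero_tolerance(self):
        aln = CodonAlignment(("a", "b"), ("ATG---CCCTTG", "ATGAAACCCTTG"))
        out = filter_blocks(aln, 0.0, 0.0, 1)
        assert out.seqs == ("ATGCCCTTG", "ATGCCCTTG")

    def test_matches_brute_force_oracle_on_random_alignments(self):
        rng = np.random.default_rng(31)
        sense = sorted(SENSE_CODONS)
        for _ in range(30):
            n_seq, n_cod = int(rng.integers(2, 6)), int(rng.integers(5, 25))
            seqs = []
            for _ in range(n_seq):
                codons = [
                    "---" if rng.random() < 0.15
                    else sense[rng.integers(0, 8)]  # few codons -> conserved-ish
                    for _ in range(n_cod)
                ]
                seqs.append("".join(codons))
            aln = CodonAlignment(tuple(f"s{i}" for i in range(n_seq)), tuple(seqs))
            expected = brute_force_filter(aln, 0.5, 0.2, 3)
            try:
                out = filter_blocks(aln, 0.5, 0.2, 3)
                got = out.seqs[0]
                want = "".join(aln.seqs[0][3 * k: 3 * k + 3] for k in expected)
                assert got == want
            except EmptyAlignmentError:
                assert expected == []

    def test_never_lengthens_and_keeps_frame(self):
        aln = CodonAlignment(("a", "b"), ("ATG---CCCTTGAAA", "ATGAAACCATTGAAA"))
        out = filter_blocks(aln, 0.5, 0.0, 2)
        assert len(out.seqs[0]) <= len(aln.seqs[0])
        assert len(out.seqs[0]) % 3 == 0


class TestNg86Sites:
    def test_phenylalanine_third_position(self):
        # of TTT's nine neighbours only TTC is synonymous -> s = 1/3
        s, n = ng86_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_tryptophan_has_no_synonymous_sites(self):
        assert ng86_sites("TGG") == (0.0, 3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_sites("TAA")

    def test_conservation_over_random_codons(self):
        rng = np.random.default_rng(13)
        sense = sorted(SENSE_CODONS)
        for i in rng.integers(0, len(sense), size=1000):
            s, n = ng86_sites(sense[i])
            assert s + n == pytest.approx(3.0, abs=1e-9)

    def test_exhaustive_neighbour_enumeration_matches(self):
        # independent oracle: enumerate the 9 neighbours inline
        for codon in sorted(SENSE_CODONS):
            syn = 0
            for pos in range(3):
                for nt in "ACGT":
                    if nt == codon[pos]:
                        continue
                    alt = codon[:pos] + nt + codon[pos + 1:]
                    if alt not in STOP_CODONS and GENETIC_CODE[alt] == GENETIC_CODE[codon]:
                        syn += 1
            assert ng86_sites(codon)[0] == pytest.approx(syn / 3)


class TestNg86KaKs:
    def test_identical_sequences_flag_ks_zero(self):
        aln = CodonAlignment(("a", "b"), ("ATGAAACCC", "ATGAAACCC"))
        res = ng86_kaks(aln)
        assert res.Ka == 0.0 and res.Ks == 0.0
        assert res.flag == "Ks_zero" and res.ratio is None

    def test_single_synonymous_change(self):
        s1 = "GGA" * 100
        s2 = "GGC" + "GGA" * 99  # one third-position synonymous change
        res = ng86_kaks(CodonAlignment(("a", "b"), (s1, s2)))
        assert res.Ka == 0.0
        assert res.Ks > 0.0

    def test_symmetry(self):
        aln, _ = simulate_codon_pair(CodonSimConfig(omega=0.5, t=0.4, length=80, seed=2))
        fwd = ng86_kaks(aln)
        rev = ng86_kaks(CodonAlignment(aln.ids[::-1], aln.seqs[::-1]))
        assert fwd.Ka == pytest.approx(rev.Ka)
        assert fwd.Ks == pytest.approx(rev.Ks)

    def test_site_count_conservation(self):
        for seed in range(10):
            aln, _ = simulate_codon_pair(
                CodonSimConfig(omega=1.0, t=0.4, length=60, seed=seed)
            )
            res = ng86_kaks(aln)
            assert res.S_sites + res.N_sites == pytest.approx(
                3 * res.compared_codons, abs=1e-9
            )
            assert res.Sd <= res.S_sites and res.Nd <= res.N_sites

    def test_gapped_codons_skipped_pairwise(self):
        aln = CodonAlignment(("a", "b"), ("ATG---CCC", "ATGAAACCC"))
        assert ng86_kaks(aln).compared_codons == 2

    def test_internal_stop_rejected_by_container(self):
        with pytest.raises(ValueError, match="stop"):
            CodonAlignment(("a", "b"), ("ATGTAACCCAAA", "ATGAAACCCAAA"))


class TestScreen:
    def _orthologs(self, n_genes=12, n_hot=2, seed=0):
        out = {}
        for g in range(n_genes):
            omega = 3.0 if g < n_hot else 0.2
            aln, _ = simulate_codon_pair(
                CodonSimConfig(omega=omega, t=0.3, length=200, seed=seed * 500 + g)
            )
            out[f"g{g:03d}"] = CodonAlignment(("focal", "comp"), aln.seqs)
        return out

    def test_planted_high_omega_genes_recovered(self):
        table, _ = screen_psg(self._orthologs(), threshold=1.0)
        hits = set(table["gene"])
        assert {"g000", "g001"} <= hits
        assert len(hits - {"g000", "g001"}) <= 1

    def test_infinite_threshold_empties_table(self):
        table, _ = screen_psg(self._orthologs(), threshold=math.inf)
        assert table.empty

    def test_gene_order_invariance(self):
        orthologs = self._orthologs()
        reordered = dict(reversed(list(orthologs.items())))
        t1, _ = screen_psg(orthologs, threshold=1.0)
        t2, _ = screen_psg(reordered, threshold=1.0)
        pd.testing.assert_frame_equal(t1, t2)

    def test_short_genes_excluded_with_log(self):
        aln, _ = simulate_codon_pair(CodonSimConfig(omega=3.0, t=0.3, length=10, seed=4))
        table, log = screen_psg(
            {"tiny": CodonAlignment(("focal", "comp"), aln.seqs)},
            threshold=1.0, min_codons=30, filter_params=None,
        )
        assert table.empty
        assert any("tiny" in line for line in log)


class TestExpressionOverlap:
    def _table(self, rows):
        return pd.DataFrame(rows).set_index("gene")

    def test_three_of_four_upregulated(self):
        tab = self._table([
            {"gene": "a", "d0": 10, "d1": 25, "d3": 9, "d7": 8},
            {"gene": "b", "d0": 10, "d1": 9, "d3": 21, "d7": 8},
            {"gene": "c", "d0": 10, "d1": 9, "d3": 9, "d7": 20},
            {"gene": "d", "d0": 10, "d1": 11, "d3": 12, "d7": 13},
        ])
        res = expression_overlap(["a", "b", "c", "d"], tab, fold_threshold=2.0)
        assert (res.numerator, res.denominator) == (3, 4)
        assert res.fraction == pytest.approx(0.75)

    def test_threshold_one_counts_any_non_decrease(self):
        tab = self._table([
            {"gene": "a", "d0": 10, "d1": 10.1, "d3": 1, "d7": 1},
            {"gene": "b", "d0": 10, "d1": 9, "d3": 9, "d7": 9},
        ])
        res = expression_overlap(["a", "b"], tab, fold_threshold=1.0)
        assert res.numerator == 1

    def test_zero_baseline_convention(self):
        tab = self._table([
            {"gene": "a", "d0": 0, "d1": 0, "d3": 5, "d7": 0},
            {"gene": "b", "d0": 0, "d1": 0, "d3": 0, "d7": 0},
        ])
        res = expression_overlap(["a", "b"], tab, fold_threshold=2.0)
        assert res.numerator == 1

    def test_missing_ids_excluded_from_denominator(self):
        tab = self._table([{"gene": "a", "d0": 1, "d1": 5, "d3": 1, "d7": 1}])
        res = expression_overlap(["a", "ghost"], tab, fold_threshold=2.0)
        assert res.denominator == 1
        assert res.missing_ids == ("ghost",)

    def test_empty_psg_set(self):
        tab = self._table([{"gene": "a", "d0": 1, "d1": 1, "d3": 1, "d7": 1}])
        res = expression_overlap([], tab)
        assert res.denominator == 0 and res.fraction is None
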