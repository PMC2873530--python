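"""Allowed-residue builders, tree weighting, and variant-space combinatorics."""

import math

import dendropy
import pytest

import epidesign as ed
from epidesign.mutability import (
    CONSERVATION_PENALTY_CAP,
    AlignmentWarning,
    conservation_penalty_of,
)

AA = ed.AMINO_ACIDS


def tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


class TestBlosumAllowed:
    def test_wildtype_always_allowed_flag_zero(self, blosum_sets, sak_peptide):
        M, pen = blosum_sets
        for i, wt in enumerate(sak_peptide, start=1):
            assert wt in M.allowed[i - 1]
            assert pen.blosum_flag[(i, wt)] == 0

    def test_proline_allows_only_itself(self):
        M, _ = ed.blosum_allowed("PPPPPPPPP", max_diff=4)
        assert all(s == frozenset("P") for s in M.allowed)

    def test_huge_cutoff_allows_everything(self, sak_peptide):
        M, _ = ed.blosum_allowed(sak_peptide, max_diff=30)
        assert all(len(s) == 20 for s in M.allowed)

    def test_tightening_cutoff_never_enlarges(self, sak_peptide):
        prev = None
        for md in (8, 4, 2, 0):
            M, _ = ed.blosum_allowed(sak_peptide, max_diff=md)
            if prev is not None:
                assert all(a <= b for a, b in zip(M.allowed, prev.allowed))
            prev = M

    def test_flag_is_indicator_of_allowed(self, blosum_sets):
        M, pen = blosum_sets
        for i, s in enumerate(M.allowed, start=1):
            for a in AA:
                assert pen.blosum_flag[(i, a)] == (0 if a in s else 1)


class TestGscWeights:
    def test_two_leaves_equal(self):
        w = ed.gsc_weights(tree("(A:1,B:1);"))
        assert w["A"] == pytest.approx(w["B"])

    def test_star_tree_uniform(self):
        w = ed.gsc_weights(tree("(A:1,B:1,C:1,D:1);"))
        assert all(v == pytest.approx(1.0) for v in w.values())

    def test_hand_worked_apportionment(self):
        # internal edge of length 1 splits 0.5/0.5 between A and B
        w = ed.gsc_weights(tree("((A:1,B:1):1,C:2);"))
        assert w == pytest.approx({"A": 1.5, "B": 1.5, "C": 2.0})

    def test_duplicated_leaf_splits_its_weight(self):
        """A zero-distance duplicate halves that leaf's weight, leaving others alone."""
        base = ed.gsc_weights(tree("((A:1,B:1):1,C:2);"))
        dup = ed.gsc_weights(tree("(((A1:0,A2:0):1,B:1):1,C:2);"))
        assert dup["A1"] == pytest.approx(base["A"] / 2)
        assert dup["A2"] == pytest.approx(base["A"] / 2)
        assert dup["B"] == pytest.approx(base["B"])
        assert dup["C"] == pytest.approx(base["C"])

    def test_all_zero_lengths_uniform_with_warning(self):
        with pytest.warns(AlignmentWarning):
            w = ed.gsc_weights(tree("(A:0,B:0,C:0);"))
        assert set(w.values()) == {1.0}

    def test_leaf_alignment_mismatch_lists_ids(self):
        t = tree("(A:1,B:1);")
        with pytest.raises(ValueError, match="C"):
            ed.weighted_alignment({"A": "MK", "B": "MK", "C": "MK"}, "A", t)


class TestConservationAllowed:
    def _walign(self, rows, weights, target):
        return ed.WeightedAlignment(rows=rows, weights=weights, target_id=target)

    def test_fully_conserved_column(self):
        wa = self._walign(
            {"t": "K", "s1": "K", "s2": "K"}, {"t": 1.0, "s1": 2.0, "s2": 0.5}, "t"
        )
        M, pen = ed.conservation_allowed(wa)
        assert M.allowed[0] == frozenset("K")
        assert pen.conservation_penalty[(1, "K")] == pytest.approx(0.0)

    def test_boundary_penalties_match_printed_range(self):
        # 5% weighted frequency -> ~3.00; 1% -> 4.61 (natural log)
        assert round(conservation_penalty_of(0.05), 2) == 3.00
        assert round(conservation_penalty_of(0.01), 2) == 4.61

    def test_weighted_frequencies_hand_computed(self):
        wa = self._walign(
            {"t": "A", "s1": "A", "s2": "V"},
            {"t": 1.5, "s1": 1.5, "s2": 2.0},
            "t",
        )
        M, pen = ed.conservation_allowed(wa, freq_min=0.05)
        assert pen.conservation_penalty[(1, "A")] == pytest.approx(-math.log(0.6))
        assert pen.conservation_penalty[(1, "V")] == pytest.approx(-math.log(0.4))
        assert M.allowed[0] == frozenset("AV")

    def test_frequencies_sum_to_one_and_penalty_decreasing(self):
        rows = {"t": "AC", "s1": "AD", "s2": "VD", "s3": "V-"}
        wa = self._walign(rows, {k: 1.0 + i for i, k in enumerate(rows)}, "t")
        for pos in (1, 2):
            freqs = wa.column_frequencies(pos)
            assert sum(freqs.values()) == pytest.approx(1.0)
            fs = sorted(freqs.values())
            pens = [conservation_penalty_of(f) for f in fs]
            assert pens == sorted(pens, reverse=True)

    def test_gap_rows_excluded_from_denominator(self):
        wa = self._walign(
            {"t": "A", "s1": "-", "s2": "A"}, {"t": 1.0, "s1": 5.0, "s2": 1.0}, "t"
        )
        assert wa.column_frequencies(1) == pytest.approx({"A": 1.0})

    def test_all_gap_column_wildtype_only_with_warning(self):
        # explicit column_map sends target position 3 (K) to the gap-only column 2
        wa = ed.WeightedAlignment(
            rows={"t": "MA-K", "s1": "MA-K"},
            weights={"t": 1.0, "s1": 1.0},
            target_id="t",
            column_map={1: 0, 2: 1, 3: 2},
        )
        with pytest.warns(AlignmentWarning, match="all-gap"):
            M, pen = ed.conservation_allowed(wa)
        assert M.allowed[2] == frozenset("K")
        assert pen.conservation_penalty[(3, "K")] == 0.0

    def test_unseen_residue_penalty_capped_and_disallowed(self):
        wa = self._walign({"t": "A", "s1": "A"}, {"t": 1.0, "s1": 1.0}, "t")
        M, pen = ed.conservation_allowed(wa)
        assert pen.conservation_penalty[(1, "W")] == pytest.approx(CONSERVATION_PENALTY_CAP)
        assert "W" not in M.allowed[0]


class TestFoldxAllowed:
    def _table(self, seq, entries):
        table = {(i, wt): 1.0 for i, wt in enumerate(seq, start=1)}
        table.update(entries)
        return table

    def test_wildtype_always_allowed_and_zero(self):
        seq = "MKV"
        M, pen = ed.foldx_allowed(seq, self._table(seq, {}), margin=0.25)
        for i, wt in enumerate(seq, start=1):
            assert wt in M.allowed[i - 1]
            assert pen.ddg[(i, wt)] == 0.0

    def test_boundary_inclusive(self):
        seq = "MKV"
        t = self._table(seq, {(1, "A"): 1.25, (2, "A"): 1.2500001})
        M, pen = ed.foldx_allowed(seq, t, margin=0.25)
        assert "A" in M.allowed[0]
        assert "A" not in M.allowed[1]
        assert pen.ddg[(1, "A")] == pytest.approx(0.25)

    def test_toy_table_matches_hand_filter(self):
        seq = "MKVLE"
        entries = {
            (1, "A"): 0.9, (1, "C"): 2.0,
            (2, "R"): 1.1, (3, "I"): 0.5, (3, "T"): 1.4,
            (4, "I"): 1.24, (5, "D"): 1.26,
        }
        M, _ = ed.foldx_allowed(seq, self._table(seq, entries), margin=0.25)
        assert M.allowed[0] == frozenset("MA")   # 0.9-1.0 = -0.1 <= 0.25
        assert M.allowed[1] == frozenset("KR")   # 0.1
        assert M.allowed[2] == frozenset("VI")   # I: -0.5 ok, T: 0.4 out
        assert M.allowed[3] == frozenset("LI")   # 0.24
        assert M.allowed[4] == frozenset("E")    # D: 0.26 > 0.25, excluded

    def test_missing_wildtype_entry_rejected(self):
        with pytest.raises(ValueError, match="positions \\[2\\]"):
            ed.foldx_allowed("MK", {(1, "M"): 0.0}, margin=0.25)


class TestVariantCombinatorics:
    def _M(self, seq, extra):
        sets = [frozenset({wt}) | frozenset(extra.get(i, "")) for i, wt in enumerate(seq, start=1)]
        return ed.AllowedResidues(seq, sets)

    def test_k_zero_is_wildtype_only(self):
        M = self._M("MKV", {1: "A"})
        assert ed.count_variants(M, 0) == 1
        assert list(ed.enumerate_variants(M, 0)) == ["MKV"]

    def test_hand_enumeration_three_positions(self):
        M = self._M("MKV", {1: "A", 2: "RS"})
        got = list(ed.enumerate_variants(M, 1))
        assert got == ["AKV", "MRV", "MSV"]
        assert ed.count_variants(M, 1) == 3

    def test_count_matches_enumeration_across_k(self):
        M = self._M("MKVLE", {1: "AC", 3: "I", 4: "TSW", 5: "D"})
        for k in range(6):
            seqs = list(ed.enumerate_variants(M, k))
            assert len(seqs) == ed.count_variants(M, k)
            assert len(set(seqs)) == len(seqs)
            assert all(sum(a != b for a, b in zip(s, "MKVLE")) == k for s in seqs)

    def test_k_beyond_length_is_zero(self):
        M = self._M("MK", {})
        assert ed.count_variants(M, 3) == 0

    def test_sak_two_substitution_space(self, blosum_sets, sak_peptide):
        M, _ = blosum_sets
        assert ed.count_variants(M, 2) == 1338
        seqs = list(ed.enumerate_variants(M, 2))
        assert len(seqs) == 1338
        assert len(set(seqs)) == 1338
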