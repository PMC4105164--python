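"""Indel characters: extraction, Fitch parsimony mapping, classification."""

import random

import dendropy
import numpy as np
import pytest

from plastcomp.alignment import Alignment
from plastcomp.phylo_indels import (
    BinaryCharacterMatrix,
    IndelCharacter,
    brute_force_min_changes,
    build_indel_matrix,
    classify_characters,
    fitch_assign,
    fitch_min_changes,
)


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestBuildMatrix:
    def test_constructed_gaps_give_expected_characters(self):
        aln = Alignment(
            rows=["ACGTACGTAA", "AC--ACGTAA", "AC--ACGTAA", "ACGTAC-TAA"],
            labels=["A", "B", "C", "D"],
        )
        m = build_indel_matrix([("r1", aln)])
        assert len(m.characters) == 2
        shared = next(c for c in m.characters if c.length == 2)
        assert shared.states == {"A": 0, "B": 1, "C": 1, "D": 0}
        assert shared.informative
        single = next(c for c in m.characters if c.length == 1)
        assert single.states["D"] == 1
        assert not single.informative

    def test_taxon_mismatch_raises(self):
        a1 = Alignment(rows=["AC-T", "ACGT"], labels=["A", "B"])
        a2 = Alignment(rows=["AC-T", "ACGT"], labels=["A", "C"])
        with pytest.raises(ValueError, match="taxa"):
            build_indel_matrix([("r1", a1), ("r2", a2)])


class TestFitch:
    def test_forced_examples(self):
        t = _tree("((A,B),(C,D));")
        assert fitch_min_changes(t, {"A": 1, "B": 1, "C": 0, "D": 0}) == 1
        assert fitch_min_changes(t, {"A": 1, "B": 0, "C": 1, "D": 0}) == 2

    @pytest.mark.parametrize("batch", range(4))
    def test_equals_exhaustive_minimum_on_random_trees(self, batch):
        rng = np.random.default_rng(500 + batch)
        for trial in range(50):
            nt = int(rng.integers(3, 9))
            taxa = [f"t{i}" for i in range(nt)]
            tree = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0,
                taxon_namespace=dendropy.TaxonNamespace(taxa),
                num_extant_tips=nt,
                rng=random.Random(batch * 100 + trial),
            )
            states = {x: int(rng.integers(0, 2)) for x in taxa}
            if rng.random() < 0.3:
                states[taxa[int(rng.integers(nt))]] = None
            assert fitch_min_changes(tree, states) == \
                brute_force_min_changes(tree, states)

    def test_invariant_to_rerooting(self):
        rng = np.random.default_rng(9)
        newick = "((A,(B,C)),((D,E),(F,(G,H))));"
        base = _tree(newick)
        states = {x: int(rng.integers(0, 2)) for x in "ABCDEFGH"}
        ref = fitch_min_changes(base, states)
        for tip in "ABCDEFGH":
            t = _tree(newick)
            node = t.find_node_with_taxon_label(tip)
            t.to_outgroup_position(node, update_bipartitions=False)
            assert fitch_min_changes(t, states) == ref


class TestAssignment:
    def _matrix(self, states_list):
        taxa = sorted(states_list[0])
        return BinaryCharacterMatrix(
            taxa=taxa,
            characters=[
                IndelCharacter(f"c{i}", "r", 1, st, True)
                for i, st in enumerate(states_list)
            ],
        )

    def test_synapomorphy_autapomorphy_homoplasy(self):
        t = _tree("((A,B),(C,D));")
        m = self._matrix([
            {"A": 1, "B": 1, "C": 0, "D": 0},   # clade gap: synapomorphy
            {"A": 1, "B": 0, "C": 0, "D": 0},   # single taxon: autapomorphy
            {"A": 1, "B": 0, "C": 1, "D": 0},   # scattered: homoplasy
        ])
        mapping = fitch_assign(t, m, outgroup="D")
        classes = [a.klass for a in mapping.assignments]
        assert classes == ["synapomorphy", "autapomorphy", "homoplasy"]
        df = classify_characters(mapping)
        assert df["class"].tolist() == classes
        assert set(df.columns) >= {"id", "region", "length", "class",
                                   "branches", "polarity"}

    def test_polarity_relative_to_outgroup(self):
        t = _tree("((A,B),(C,D));")
        m = self._matrix([
            {"A": 1, "B": 1, "C": 0, "D": 0},   # gap gained: deletion
            {"A": 0, "B": 0, "C": 1, "D": 1},   # outgroup has gap: insertion
        ])
        mapping = fitch_assign(t, m, outgroup="D")
        assert mapping.assignments[0].polarity == "-"
        assert mapping.assignments[1].polarity == "+"

    def test_all_autapomorphies_no_homoplasy(self):
        t = _tree("((A,B),(C,D));")
        m = self._matrix([
            {"A": 1, "B": 0, "C": 0, "D": 0},
            {"A": 0, "B": 1, "C": 0, "D": 0},
            {"A": 0, "B": 0, "C": 1, "D": 0},
        ])
        mapping = fitch_assign(t, m, outgroup="D")
        assert all(a.klass == "autapomorphy" for a in mapping.assignments)

    def test_characters_from_single_branch_mutations_map_cleanly(self):
        """Characters generated by one mutation on a known branch classify as
        synapomorphy or autapomorphy, never homoplasy, on the true tree."""
        newick = "((A,B),((C,D),E));"
        t = _tree(newick)
        clades = [("A",), ("B",), ("A", "B"), ("C", "D"), ("C", "D", "E")]
        states_list = [
            {x: (1 if x in clade else 0) for x in "ABCDE"}
            for clade in clades
        ]
        mapping = fitch_assign(t, self._matrix(states_list), outgroup="E")
        for clade, asg in zip(clades, mapping.assignments):
            assert asg.min_changes == 1
            expect = "autapomorphy" if len(clade) == 1 else "synapomorphy"
            if set(clade) == {"C", "D", "E"}:
                # with E as outgroup the derived side is the (A,B) clade
                expect = "synapomorphy"
            assert asg.klass == expect

    def test_class_partition_is_total(self):
        rng = np.random.default_rng(123)
        t = _tree("((A,(B,C)),((D,E),F));")
        states_list = []
        for _ in range(30):
            st = {x: int(rng.integers(0, 2)) for x in "ABCDEF"}
            if len(set(st.values())) < 2:
                continue
            states_list.append(st)
        mapping = fitch_assign(t, self._matrix(states_list), outgroup="F")
        for a in mapping.assignments:
            assert a.klass in ("synapomorphy", "autapomorphy", "homoplasy")
            if a.min_changes == 1:
                assert a.klass in ("synapomorphy", "autapomorphy")
            else:
                assert a.klass == "homoplasy"
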