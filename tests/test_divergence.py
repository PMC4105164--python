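"""Alignment scores, event counting, the variability formula and ratios."""

import numpy as np
import pytest

from plastcomp.alignment import Alignment, align_multi, align_pair
from plastcomp.divergence import (
    count_events,
    count_events_multi,
    indel_length_spectrum,
    screen_markers,
    si_ratio,
    variability_percent,
)

from _oracles import brute_align_score, score_alignment_rows


class TestAlignPair:
    def test_identical_sequences_align_without_gaps(self, rng):
        s = "".join(rng.choice(list("ACGT"), 100))
        aln = align_pair(s, s)
        assert aln.rows[0] == aln.rows[1] == s

    def test_forced_single_gap(self):
        aln = align_pair("ACGT", "AGT")
        d = count_events(aln)
        assert d.indels == 0 or d.indels == 1   # terminal exclusion applies
        events = count_events(aln, exclude_terminal_gaps=False)
        assert events.indels == 1
        assert events.indel_events[0].length == 1

    @pytest.mark.parametrize("trial", range(60))
    def test_score_equals_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(3000 + trial)
        a = "".join(rng.choice(list("ACGT"), int(rng.integers(1, 9))))
        b = "".join(rng.choice(list("ACGT"), int(rng.integers(1, 9))))
        aln = align_pair(a, b)
        exp = brute_align_score(a, b)
        assert aln.score == exp
        assert score_alignment_rows(*aln.rows) == exp

    def test_oversize_input_rejected(self):
        with pytest.raises(ValueError, match="region-wise"):
            align_pair("A" * 30000, "A" * 30000)


class TestCountEvents:
    def test_constructed_example(self):
        aln = Alignment(rows=["AACG-TT", "AATGCTT"], labels=["x", "y"])
        d = count_events(aln)
        assert d.substitutions == 1
        assert d.subs_by_type[frozenset(("C", "T"))] == 1
        assert d.indels == 1
        assert d.indel_events[0].length == 1

    def test_identical_rows(self):
        d = count_events(Alignment(rows=["ACGT", "ACGT"]))
        assert d.substitutions == 0 and d.indels == 0

    def test_n_columns_excluded_from_substitutions(self):
        d = count_events(Alignment(rows=["ANGT", "ATGA"]))
        assert d.substitutions == 1      # only the T/A column

    def test_type_counts_sum_to_ns(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), 60))
            b = "".join(rng.choice(list("ACGT"), 60))
            d = count_events(Alignment(rows=[a, b]))
            assert sum(d.subs_by_type.values()) == d.substitutions

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            a = "".join(rng.choice(list("ACGT"), int(rng.integers(30, 90))))
            b = list(a)
            for p in rng.choice(len(b), size=5, replace=False):
                b[p] = str(rng.choice(list("ACGT")))
            b = "".join(b)
            ab = count_events(align_multi({"a": a, "b": b}))
            ba = count_events(align_multi({"b": b, "a": a}))
            assert ab.substitutions == ba.substitutions
            assert ab.indels == ba.indels


class TestSiRatio:
    def test_reported_ratios_round_to_two_decimals(self):
        assert si_ratio(82, 28) == 2.93
        assert si_ratio(265, 53) == 5.00
        assert si_ratio(0, 5) == 0.00

    def test_undefined_when_no_indels(self):
        with pytest.raises(ZeroDivisionError):
            si_ratio(10, 0)


class TestSpectrum:
    def test_binning(self):
        from plastcomp.divergence import IndelEvent

        events = [IndelEvent(l, 0, (0,)) for l in (1, 1, 5)]
        df = indel_length_spectrum(events).set_index("bin")
        assert df.loc["1", "count"] == 2
        assert df.loc["5-6", "count"] == 1
        assert df["fraction"].sum() == pytest.approx(1.0)


class TestVariability:
    def test_identical_rows_zero(self):
        v = variability_percent(Alignment(rows=["ACGT" * 10] * 3))
        assert v.variability_percent == 0.0

    def test_formula_on_constructed_alignment(self):
        base = list("A" * 100)
        r1 = "".join(base)
        r2 = list(base)
        r2[10] = "G"                       # one variable column
        r2[50:53] = "---"                  # one 3-column gap block
        v = variability_percent(Alignment(rows=[r1, "".join(r2)]))
        assert v.ns == 1 and v.id_ == 1 and v.aligned_length == 100
        assert v.variability_percent == pytest.approx(2.0)

    def test_multi_row_gap_blocks_count_once_per_pattern(self):
        rows = ["ACGTACGTAC",
                "AC--ACGTAC",
                "AC--ACGTAC",
                "ACGTAC--AC"]
        ns, id_ = count_events_multi(Alignment(rows=rows))
        assert id_ == 2      # the shared 2-col block and the distinct one
        assert ns == 0

    def test_bounds_always_hold(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), 50))
            b = "".join(rng.choice(list("ACGT"), 45))
            v = variability_percent(align_multi({"a": a, "b": b}))
            assert 0.0 <= v.variability_percent <= 100.0


class TestScreen:
    def _var(self, name, cat, ns, id_, L):
        from plastcomp.divergence import RegionVariability

        return RegionVariability(name, cat, ns, id_, L)

    def test_strict_threshold_and_ordering(self):
        vs = [
            self._var("a/b", "non-coding", 3, 1, 100),   # 4.0
            self._var("c/d", "non-coding", 1, 0, 100),   # 1.0
            self._var("e", "coding", 10, 0, 100),        # wrong category
            self._var("f/g", "non-coding", 1, 1, 100),   # 2.0
        ]
        out = screen_markers(vs, threshold=1.5)
        assert [v.name for v in out] == ["a/b", "f/g"]

    def test_all_zero_empty(self):
        assert screen_markers(
            [self._var("x", "non-coding", 0, 0, 50)]
        ) == []
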