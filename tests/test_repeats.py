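"""Dispersed-repeat detection against the exhaustive diagonal-scan oracle."""

import numpy as np
import pytest

from plastcomp._dna import revcomp
from plastcomp.quadripartite import detect_quadripartite
from plastcomp.repeats import (
    RepeatHit,
    find_repeats,
    shared_repeat_sets,
    strip_duplicate_ir,
)

from _oracles import brute_repeats, plant_repeat_pair

def _plant_exact_pair(rng, bg, x, at1, at2):
    """Plant two exact copies with mismatched flanks so the pair cannot
    extend beyond the planted length."""
    s = list(bg[:at1] + x + bg[at1:at2] + x + bg[at2:])
    p1, p2 = at1, at2 + len(x)
    L = len(x)
    for (a, b) in ((p1 - 1, p2 - 1), (p1 + L, p2 + L)):
        if s[a] == s[b]:
            s[b] = next(c for c in "ACGT" if c != s[a])
    return "".join(s), p1, p2


def _as_keys(hits):
    return {(h.type, h.pos1, h.pos2, h.length, h.mismatches) for h in hits}


@pytest.mark.parametrize("trial", range(6))
def test_finder_equals_brute_force_on_random_sequences(trial):
    rng = np.random.default_rng(1000 + trial)
    n = int(rng.integers(200, 700))
    nspec = int(rng.integers(0, 3))
    specs = [
        (
            ["direct", "reverse", "palindromic"][int(rng.integers(3))],
            int(rng.integers(25, 61)),
            int(rng.integers(0, 4)),
        )
        for _ in range(nspec)
    ]
    seq, _ = plant_repeat_pair(rng, n, specs)
    got = _as_keys(find_repeats(seq, min_len=25))
    assert got == brute_repeats(seq, min_len=25)


def test_simple_planted_pairs(rng):
    bg = "".join(rng.choice(list("ACGT"), 200))
    x = "".join(rng.choice(list("ACGT"), 30))
    seq = bg[:50] + x + bg[50:120] + x + bg[120:]
    hits = [h for h in find_repeats(seq) if h.type == "direct"]
    assert any(
        h.pos1 <= 50 and h.pos1 + h.length >= 80 and h.mismatches <= 3
        for h in hits
    )
    seq2 = bg[:50] + x + bg[50:120] + revcomp(x) + bg[120:]
    hits2 = [h for h in find_repeats(seq2) if h.type == "palindromic"]
    assert any(h.length >= 30 for h in hits2)


def test_length_threshold_is_sharp_without_mismatches(rng):
    """With the mismatch budget off, 30 bp plants are found, 29 bp never."""
    for trial in range(10):
        r = np.random.default_rng(7000 + trial)
        bg = "".join(r.choice(list("ACGT"), 400))
        x29 = "".join(r.choice(list("ACGT"), 29))
        x30 = "".join(r.choice(list("ACGT"), 30))
        s29, _, _ = _plant_exact_pair(r, bg, x29, 100, 250)
        s30, _, _ = _plant_exact_pair(r, bg, x30, 100, 250)
        assert find_repeats(s29, max_mismatch=0) == []
        hits = find_repeats(s30, max_mismatch=0)
        assert any(h.type == "direct" and h.length >= 30 for h in hits)


def test_invariance_under_reverse_complement(rng):
    seq, _ = plant_repeat_pair(
        np.random.default_rng(42), 500,
        [("direct", 35, 1), ("palindromic", 40, 0), ("reverse", 32, 2)],
    )
    fwd = find_repeats(seq, min_len=25)
    rev = find_repeats(revcomp(seq), min_len=25)
    n = len(seq)

    def remap(h):
        p1 = n - (h.pos2 + h.length)
        p2 = n - (h.pos1 + h.length)
        return (h.type, p1, p2, h.length, h.mismatches)

    assert {remap(h) for h in rev} == _as_keys(fwd)


def test_every_hit_verifies_its_own_identity(rng):
    seq, _ = plant_repeat_pair(
        np.random.default_rng(9), 600, [("direct", 50, 3), ("reverse", 40, 1)]
    )
    for h in find_repeats(seq, min_len=25):
        a = seq[h.pos1 : h.pos1 + h.length]
        b = seq[h.pos2 : h.pos2 + h.length]
        if h.type == "palindromic":
            b = revcomp(b)
        elif h.type == "reverse":
            b = b[::-1]
        ham = sum(c1 != c2 for c1, c2 in zip(a, b))
        assert ham == h.mismatches
        assert ham <= min(3, h.length // 10)
        assert h.pos2 >= h.pos1 + h.length


def test_min_len_below_seed_scheme_raises():
    with pytest.raises(ValueError):
        find_repeats("ACGT" * 100, min_len=6)


def test_strip_duplicate_ir_length_and_single_copy(small_ancestor):
    rec, truth = small_ancestor
    part = detect_quadripartite(rec, min_ir=1000)
    stripped, meta = strip_duplicate_ir(rec, part)
    assert len(stripped) == len(rec.sequence) - part.ir_length
    assert meta["ir_length_removed"] == part.ir_length
    # no large inverted self-match remains
    from plastcomp.genome_io import PlastomeRecord
    from plastcomp.quadripartite import NoQuadripartiteError

    with pytest.raises(NoQuadripartiteError):
        detect_quadripartite(
            PlastomeRecord("s", stripped), min_ir=part.ir_length
        )


def test_planted_repeats_recovered_from_stripped_sequence(small_ancestor):
    rec, truth = small_ancestor
    stripped = rec.sequence[: truth.boundaries[2]]    # LSC + IRb + SSC
    hits = find_repeats(stripped)
    for pr in truth.planted_repeats:
        covered = any(
            h.type == pr.type
            and h.pos1 <= pr.pos1 and pr.pos1 + pr.length <= h.pos1 + h.length
            and h.pos2 <= pr.pos2 and pr.pos2 + pr.length <= h.pos2 + h.length
            for h in hits
        )
        assert covered, f"planted {pr} not recovered"


class TestSharedRepeats:
    def _hit(self, rtype, length, r1, r2):
        return RepeatHit(rtype, length, 0, 100, 0,
                         region_name1=r1, region_name2=r2)

    def test_identical_genomes_share_everything(self):
        hits = [self._hit("direct", 30, "a/b", "c/d"),
                self._hit("reverse", 31, "a/b", "e/f")]
        summary = shared_repeat_sets({"g1": hits, "g2": list(hits)})
        assert summary.shared_all == 2
        assert summary.unique_per_genome == {"g1": 0, "g2": 0}

    def test_planted_shared_and_private_counts(self):
        shared = self._hit("direct", 30, "x/y", "u/v")
        only1 = self._hit("palindromic", 44, "x/y", "w/z")
        only2 = self._hit("reverse", 35, "p/q", "u/v")
        summary = shared_repeat_sets(
            {"g1": [shared, only1], "g2": [shared, only2]}
        )
        assert summary.shared_all == 1
        assert summary.unique_per_genome == {"g1": 1, "g2": 1}
        assert summary.shared_by == {2: 1, 1: 2}
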