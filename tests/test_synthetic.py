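"""The synthetic plastome generator: determinism, replay, invariants."""

import numpy as np
import pytest

from plastcomp._dna import revcomp
from plastcomp.genome_io import read_fasta, read_genbank
from plastcomp.quadripartite import detect_quadripartite
from plastcomp.synthetic_data import (
    AncestorConfig,
    EvolutionConfig,
    evolve_along_tree,
    make_ancestor,
    path_events,
    replay,
    write_fixture_set,
)


def test_fixed_seed_is_byte_identical():
    cfg = AncestorConfig(lsc_len=6000, ssc_len=1500, ir_len=2000, seed=5)
    r1, _ = make_ancestor(cfg)
    r2, _ = make_ancestor(
        AncestorConfig(lsc_len=6000, ssc_len=1500, ir_len=2000, seed=5)
    )
    assert r1.sequence == r2.sequence
    assert [(f.name, f.intervals) for f in r1.features] == \
        [(f.name, f.intervals) for f in r2.features]


def test_zero_gene_config_gives_sequence_only():
    cfg = AncestorConfig(lsc_len=6000, ssc_len=1500, ir_len=2000,
                         with_genes=False, n_ssr_mono=0, n_ssr_hexa=0,
                         n_repeats=0, seed=1)
    rec, truth = make_ancestor(cfg)
    assert rec.features == []
    assert len(rec.sequence) == cfg.genome_length


def test_detection_recovers_planted_structure_exactly(small_ancestor):
    rec, truth = small_ancestor
    part = detect_quadripartite(rec, min_ir=1000)
    b1, b2, b3, b4 = truth.boundaries
    assert part.junctions == {"JLB": b1, "JSB": b2, "JSA": b3, "JLA": 0}


def test_gc_near_target(small_ancestor):
    rec, truth = small_ancestor
    assert abs(rec.gc_percent / 100 - truth.config.gc_fraction) < 0.02


def test_zero_branch_lengths_leave_tips_identical(small_ancestor):
    rec, truth0 = small_ancestor
    tips, _ = evolve_along_tree(
        rec, truth0, EvolutionConfig(tree="(A:0.0,B:0.0);", seed=3)
    )
    assert tips["A"].sequence == rec.sequence
    assert tips["B"].sequence == rec.sequence


def test_negative_branch_length_raises(small_ancestor):
    rec, truth0 = small_ancestor
    with pytest.raises(ValueError, match="negative"):
        evolve_along_tree(
            rec, truth0, EvolutionConfig(tree="(A:-0.1,B:0.1);", seed=3)
        )


def test_replay_reproduces_every_tip(small_study):
    rec, tips, truth, _ = small_study
    for label, tip in tips.items():
        assert replay(rec.sequence, path_events(truth, label)) \
            == tip.sequence


def test_concerted_evolution_invariant(small_study):
    rec, tips, truth, _ = small_study
    for label, tip in tips.items():
        b1, b2, b3, b4 = truth.tip_boundaries[label]
        assert tip.sequence[b3:b4] == revcomp(tip.sequence[b1:b2])


def test_without_concerted_evolution_copies_diverge(small_ancestor):
    rec, truth0 = small_ancestor
    tips, truth = evolve_along_tree(
        rec, truth0,
        EvolutionConfig(tree="(A:0.02,B:0.02);", seed=6, ir_concerted=False),
    )
    diverged = 0
    for label, tip in tips.items():
        b1, b2, b3, b4 = truth.tip_boundaries[label]
        if tip.sequence[b3:b4] != revcomp(tip.sequence[b1:b2]):
            diverged += 1
    assert diverged == 2


def test_annotations_lifted_through_indels(small_study):
    rec, tips, truth, _ = small_study
    for tip in tips.values():
        n = len(tip.sequence)
        assert tip.features, "annotations lost"
        for f in tip.features:
            for s, e, _ in f.intervals:
                assert 0 <= s <= e <= n


def test_mixture_must_sum_to_one():
    with pytest.raises(ValueError, match="sum to 1"):
        EvolutionConfig(tree="(A:1,B:1);",
                        indel_length_mix={"1": 0.5, "2": 0.1})


def test_fixture_round_trip(small_study, tmp_path):
    rec, tips, truth, tree = small_study
    files = write_fixture_set(tips, truth, tree, tmp_path / "fix")
    assert files
    for label, tip in tips.items():
        gb = read_genbank(tmp_path / "fix" / f"{label}.gb")
        fa = read_fasta(tmp_path / "fix" / f"{label}.fasta")[0]
        assert gb.sequence == tip.sequence
        assert fa.sequence == tip.sequence
    assert (tmp_path / "fix" / "tree.nwk").read_text().strip() == tree


def test_empty_tip_map_writes_nothing(tmp_path, small_ancestor):
    _, truth = small_ancestor
    assert write_fixture_set({}, truth, "(A,B);", tmp_path / "e") == []
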