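"""Record IO, functional-region extraction and gene statistics."""

import pytest

from plastcomp.genome_io import (
    CoordinateError,
    Feature,
    FormatError,
    PlastomeRecord,
    classify_location,
    extract_functional_regions,
    find_gene_overlaps,
    gene_census,
    read_fasta,
    read_genbank,
    write_fasta,
    write_genbank,
)


def test_minimal_record_has_one_feature(toy_record):
    assert len(toy_record.features) == 2
    assert toy_record.genes()[0].intervals == [(9, 40, "+")]


def test_genbank_round_trip_preserves_sequence_and_features(
    small_ancestor, tmp_path
):
    rec, _ = small_ancestor
    path = tmp_path / "anc.gb"
    write_genbank(rec, path)
    back = read_genbank(path)
    assert back.sequence == rec.sequence
    assert back.circular
    got = {(f.name, f.kind, tuple(f.intervals)) for f in back.features}
    want = {(f.name, f.kind, tuple(f.intervals)) for f in rec.features}
    assert got == want


def test_fasta_round_trip_and_normalisation(small_ancestor, tmp_path):
    rec, _ = small_ancestor
    path = tmp_path / "anc.fasta"
    write_fasta([rec], path)
    back = read_fasta(path)[0]
    assert back.sequence == rec.sequence
    # lowercase and unknown symbols
    p2 = tmp_path / "odd.fasta"
    p2.write_text(">x\nacgtxr\n")
    odd = read_fasta(p2)[0]
    assert odd.sequence == "ACGTNN"
    with pytest.raises(FormatError):
        read_fasta(tmp_path / "empty.fasta") if (
            (tmp_path / "empty.fasta").write_text("") or True
        ) else None


def test_igs_extraction_with_wraparound():
    rec = PlastomeRecord(
        id="t", sequence="A" * 400, circular=True,
        features=[
            Feature("A", "gene", [(0, 100, "+")]),
            Feature("B", "gene", [(200, 300, "+")]),
        ],
    )
    rs = extract_functional_regions(rec)
    igs = dict(rs.by_category("IGS"))
    assert igs["A/B"] == [(100, 200)]
    assert igs["B/A"] == [(300, 400)]         # wrap back to gene A at 0


def test_intron_from_exon_gap():
    rec = PlastomeRecord(
        id="t", sequence="A" * 200, circular=False,
        features=[
            Feature("g", "gene", [(0, 120, "+")]),
            Feature("g", "CDS", [(0, 50, "+"), (80, 120, "+")]),
        ],
    )
    rs = extract_functional_regions(rec)
    introns = dict(rs.by_category("intron"))
    assert introns["g intron"] == [(50, 80)]


def test_region_coverage_on_synthetic_genome(small_ancestor):
    """Gene spans plus IGS minus overlaps tile the whole genome."""
    rec, _ = small_ancestor
    rs = extract_functional_regions(rec)
    n = len(rec.sequence)
    covered = [False] * n
    for g in rec.genes():
        for s, e, _ in g.intervals:
            for i in range(s, e):
                covered[i] = True
    for _, ivs in rs.by_category("IGS"):
        for s, e in ivs:
            for i in range(s, e):
                covered[i] = True
    assert all(covered)


def test_gene_census_matches_planted_truth(small_ancestor):
    rec, truth = small_ancestor
    census = gene_census(rec)
    assert census.total == truth.gene_counts["total"]
    assert census.trna == truth.gene_counts.get("trna", 0)
    assert census.rrna == truth.gene_counts.get("rrna", 0)
    assert census.protein_coding == truth.gene_counts.get("protein", 0)
    assert census.total == census.protein_coding + census.trna + census.rrna


def test_census_empty_for_unannotated_record():
    rec = PlastomeRecord(id="x", sequence="ACGT", features=[])
    c = gene_census(rec)
    assert (c.total, c.protein_coding, c.trna, c.rrna, c.intron_containing) \
        == (0, 0, 0, 0, 0)


def test_planted_gene_overlaps_are_detected(small_ancestor):
    rec, _ = small_ancestor
    overlaps = {(a, b): ov for a, b, ov in find_gene_overlaps(rec)}
    joined = {frozenset(k): v for k, v in overlaps.items()}
    if frozenset(("psbD", "psbC")) in joined:
        assert joined[frozenset(("psbD", "psbC"))] == 52
    if frozenset(("atpB", "atpE")) in joined:
        assert joined[frozenset(("atpB", "atpE"))] == 3


def test_no_overlaps_for_disjoint_genes():
    rec = PlastomeRecord(
        id="t", sequence="A" * 300,
        features=[
            Feature("A", "gene", [(0, 100, "+")]),
            Feature("B", "gene", [(150, 250, "+")]),
        ],
    )
    assert find_gene_overlaps(rec) == []


class TestClassifyLocation:
    def test_single_category(self):
        rec = PlastomeRecord(
            id="t", sequence="A" * 400,
            features=[
                Feature("A", "gene", [(0, 100, "+")]),
                Feature("A", "CDS", [(0, 100, "+")]),
                Feature("B", "gene", [(200, 300, "+")]),
                Feature("B", "CDS", [(200, 300, "+")]),
                Feature("trnX", "gene", [(320, 380, "+")]),
                Feature("trnX", "tRNA", [(320, 380, "+")]),
            ],
        )
        rs = extract_functional_regions(rec)
        assert classify_location((120, 180), rs) == ("IGS", "A/B")
        assert classify_location((10, 50), rs) == ("CDS", "A")
        assert classify_location((80, 120), rs)[0] == "CDS-IGS"
        # the whole genome touches three or more categories
        assert classify_location((0, 400), rs)[0] == "mixed"
        with pytest.raises(CoordinateError):
            classify_location((390, 500), rs)

    def test_every_inbounds_interval_gets_exactly_one_class(
        self, small_ancestor, rng
    ):
        rec, _ = small_ancestor
        rs = extract_functional_regions(rec)
        n = len(rec.sequence)
        for _ in range(100):
            s = int(rng.integers(0, n - 50))
            w = int(rng.integers(1, 50))
            cls, _name = classify_location((s, s + w), rs)
            assert isinstance(cls, str) and cls
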