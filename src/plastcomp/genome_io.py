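"""Plastome records: reading, writing, functional regions and gene statistics.

Coordinates are 0-based half-open on the forward strand throughout; GenBank's
1-based closed locations are converted at the parsing boundary.  Features that
wrap the circular origin are stored as two intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from ._dna import gc_fraction

log = logging.getLogger(__name__)

GENE_KINDS = {"gene", "CDS", "tRNA", "rRNA", "exon", "intron", "other"}

#: ordering used when building hyphenated location classes such as "CDS-IGS"
CATEGORY_ORDER = ["CDS", "intron", "IGS", "tRNA", "rRNA"]


class FormatError(ValueError):
    """Raised for malformed input files."""


class CoordinateError(ValueError):
    """Raised when an interval falls outside the genome."""


@dataclass
class Feature:
    """One annotated element, possibly multi-interval (exons) or origin-wrapping."""

    name: str
    kind: str
    intervals: list[tuple[int, int, str]]
    copy_tag: str | None = None

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError(f"feature {self.name!r} has no intervals")
        if self.kind not in GENE_KINDS:
            raise ValueError(f"feature {self.name!r}: unknown kind {self.kind!r}")
        for s, e, strand in self.intervals:
            if strand not in "+-":
                raise ValueError(f"feature {self.name!r}: bad strand {strand!r}")
            if e < s:
                raise ValueError(f"feature {self.name!r}: interval ({s},{e}) reversed")

    @property
    def start(self) -> int:
        return min(s for s, _, _ in self.intervals)

    @property
    def end(self) -> int:
        return max(e for _, e, _ in self.intervals)

    @property
    def strand(self) -> str:
        return self.intervals[0][2]

    def span_length(self) -> int:
        return sum(e - s for s, e, _ in self.intervals)


@dataclass
class PlastomeRecord:
    id: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        n = len(self.sequence)
        for f in self.features:
            for s, e, _ in f.intervals:
                if not (0 <= s <= e <= n):
                    raise CoordinateError(
                        f"feature {f.name!r} interval ({s},{e}) outside genome of {n} bp"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc_percent(self) -> float:
        return 100.0 * gc_fraction(self.sequence)

    def genes(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "gene"]


@dataclass
class RegionSet:
    """Named functional regions (CDS, intron, IGS, tRNA, rRNA) of one genome."""

    regions: list[tuple[str, str, list[tuple[int, int]]]]
    genome_length: int = 0

    def by_category(self, category: str) -> list[tuple[str, list[tuple[int, int]]]]:
        return [(n, iv) for n, c, iv in self.regions if c == category]

    def total_length(self, category: str) -> int:
        return sum(e - s for _, iv in self.by_category(category) for s, e in iv)


@dataclass
class GeneCensus:
    total: int
    protein_coding: int
    trna: int
    rrna: int
    intron_containing: int
    two_intron_genes: list[str]

    def __post_init__(self) -> None:
        assert self.total == self.protein_coding + self.trna + self.rrna


# ---------------------------------------------------------------------------
# reading / writing


def _location_to_intervals(location) -> list[tuple[int, int, str]]:
    strand = "-" if location.strand == -1 else "+"
    parts = location.parts if isinstance(location, CompoundLocation) else [location]
    ivs = [(int(p.start), int(p.end), strand) for p in parts]
    if strand == "-":
        ivs = ivs[::-1] if ivs[0][0] > ivs[-1][0] else ivs
    return sorted(ivs)


def read_genbank(path: str | Path) -> PlastomeRecord:
    """Parse a GenBank flat file into a :class:`PlastomeRecord`.

    join()/complement() locations become interval lists; the circular flag is
    taken from the LOCUS topology.
    """
    try:
        rec = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise FormatError(f"{path}: no GenBank record found") from None
    seq = str(rec.seq).upper()
    if not seq or set(seq) == {"N"} and len(seq) == 0:
        raise FormatError(f"{path}: record has no sequence")
    feats: list[Feature] = []
    for f in rec.features:
        if f.type not in ("gene", "CDS", "tRNA", "rRNA"):
            continue
        name = (
            f.qualifiers.get("gene", [None])[0]
            or f.qualifiers.get("locus_tag", ["?"])[0]
        )
        ivs = _location_to_intervals(f.location)
        for s, e, _ in ivs:
            if e > len(seq) or s < 0:
                raise CoordinateError(
                    f"{path}: feature {name!r} interval ({s},{e}) beyond sequence"
                )
        tag = f.qualifiers.get("note", [None])[0]
        copy_tag = tag if tag in ("IRa", "IRb") else None
        feats.append(Feature(name=name, kind=f.type, intervals=ivs, copy_tag=copy_tag))
    circular = rec.annotations.get("topology", "linear") == "circular"
    return PlastomeRecord(
        id=rec.id or rec.name, sequence=seq, circular=circular,
        features=feats, source=str(path),
    )


def write_genbank(record: PlastomeRecord, path: str | Path) -> None:
    seqrec = SeqRecord(Seq(record.sequence), id=record.id, name=record.id[:16],
                       description="")
    seqrec.annotations["molecule_type"] = "DNA"
    seqrec.annotations["topology"] = "circular" if record.circular else "linear"
    for f in record.features:
        strand = -1 if f.strand == "-" else 1
        locs = [SimpleLocation(s, e, strand) for s, e, _ in f.intervals]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [f.name]}
        if f.copy_tag:
            quals["note"] = [f.copy_tag]
        seqrec.features.append(SeqFeature(loc, type=f.kind, qualifiers=quals))
    SeqIO.write([seqrec], str(path), "genbank")


def read_fasta(path: str | Path, circular: bool = True) -> list[PlastomeRecord]:
    """Read FASTA into feature-less records; non-ACGTN symbols become N."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = sum(1 for c in seq if c not in "ACGTN")
        if bad:
            log.warning("%s:%s: %d non-ACGTN symbols mapped to N", path, rec.id, bad)
            seq = "".join(c if c in "ACGTN" else "N" for c in seq)
        records.append(PlastomeRecord(id=rec.id, sequence=seq, circular=circular,
                                      features=[], source=str(path)))
    if not records:
        raise FormatError(f"{path}: empty FASTA")
    return records


def write_fasta(records: Iterable[PlastomeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.sequence), 70):
                fh.write(r.sequence[i : i + 70] + "\n")


def write_feature_table(record: PlastomeRecord, path: str | Path) -> None:
    """TSV feature table: record, name, kind, start, end, strand, copy_tag."""
    with open(path, "w") as fh:
        fh.write("record\tname\tkind\tstart\tend\tstrand\tcopy_tag\n")
        for f in record.features:
            for s, e, strand in f.intervals:
                fh.write(
                    f"{record.id}\t{f.name}\t{f.kind}\t{s}\t{e}\t{strand}\t"
                    f"{f.copy_tag or ''}\n"
                )


# ---------------------------------------------------------------------------
# functional regions

#: inter-exon gaps larger than this are not called introns (keeps the
#: trans-spliced rps12 parts from producing a partition-spanning "intron";
#: the largest genuine plastid intron here is ~2.5 kb).
MAX_INTRON = 5000


def _merged_span(feature: Feature) -> tuple[int, int]:
    return feature.start, feature.end


def _intron_gaps(feature: Feature) -> list[tuple[int, int]]:
    gaps = []
    ivs = sorted(feature.intervals)
    for (s1, e1, _), (s2, e2, _) in zip(ivs, ivs[1:]):
        if 0 < s2 - e1 <= MAX_INTRON:
            gaps.append((e1, s2))
    return gaps


def extract_functional_regions(record: PlastomeRecord) -> RegionSet:
    """Derive named CDS, intron, IGS, tRNA and rRNA regions from annotation.

    IGS regions are maximal inter-gene gaps named ``geneA/geneB`` in genome
    order; zero-length spacers between abutting or overlapping genes are
    omitted.  Introns are inter-exon gaps of one feature copy, named
    ``gene intron`` with an ordinal suffix for two-intron genes.
    """
    genes = record.genes()
    if not genes:
        raise ValueError(f"record {record.id!r} has no gene features")
    n = len(record.sequence)
    regions: list[tuple[str, str, list[tuple[int, int]]]] = []

    # coding / structural-RNA exon intervals and introns
    intron_ordinal: dict[str, int] = {}
    for f in record.features:
        if f.kind in ("CDS", "tRNA", "rRNA"):
            regions.append((f.name, f.kind if f.kind != "CDS" else "CDS",
                            [(s, e) for s, e, _ in f.intervals]))
            gaps = _intron_gaps(f)
            if len(gaps) == 1:
                regions.append((f"{f.name} intron", "intron", [gaps[0]]))
            else:
                for i, g in enumerate(gaps, 1):
                    regions.append((f"{f.name} intron {i}", "intron", [g]))

    # IGS between consecutive gene spans, walking the circle
    spans = sorted((_merged_span(g), g.name) for g in genes)
    merged: list[tuple[int, int, str]] = []  # strictly increasing, overlap-merged ends
    for (s, e), name in spans:
        if merged and s < merged[-1][1]:
            # overlapping genes: extend the block, keep the rightmost name
            ps, pe, pn = merged[-1]
            merged[-1] = (ps, max(pe, e), name if e > pe else pn)
        else:
            merged.append((s, e, name))
    for (s1, e1, n1), (s2, e2, n2) in zip(merged, merged[1:]):
        if s2 > e1:
            regions.append((f"{n1}/{n2}", "IGS", [(e1, s2)]))
    if record.circular and merged:
        s_first, _, n_first = merged[0]
        _, e_last, n_last = merged[-1]
        wrap = (n - e_last) + s_first
        if wrap > 0:
            ivs = [(e_last, n)] if s_first == 0 else [(e_last, n), (0, s_first)]
            ivs = [iv for iv in ivs if iv[1] > iv[0]]
            if ivs:
                regions.append((f"{n_last}/{n_first}", "IGS", ivs))
    return RegionSet(regions=regions, genome_length=n)


def gene_census(record: PlastomeRecord) -> GeneCensus:
    """Count annotated gene instances (IR duplicates count separately)."""
    genes = record.genes()
    trna = sum(1 for g in genes if g.name.startswith("trn"))
    rrna = sum(1 for g in genes if g.name.startswith("rrn"))
    protein = len(genes) - trna - rrna
    introns_per_name: dict[str, int] = {}
    for f in record.features:
        if f.kind in ("CDS", "tRNA", "rRNA", "gene"):
            gaps = _intron_gaps(f)
            if gaps:
                introns_per_name[f.name] = max(
                    introns_per_name.get(f.name, 0), len(gaps)
                )
    return GeneCensus(
        total=len(genes),
        protein_coding=protein,
        trna=trna,
        rrna=rrna,
        intron_containing=len(introns_per_name),
        two_intron_genes=sorted(k for k, v in introns_per_name.items() if v >= 2),
    )


def find_gene_overlaps(record: PlastomeRecord) -> list[tuple[str, str, int]]:
    """All unordered gene pairs whose genomic spans overlap, with overlap bp."""
    out = []
    genes = record.genes()
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            ov = 0
            for s1, e1, _ in a.intervals:
                for s2, e2, _ in b.intervals:
                    ov += max(0, min(e1, e2) - max(s1, s2))
            if ov > 0 and a.name != b.name:
                out.append((a.name, b.name, ov))
    return sorted(out, key=lambda t: -t[2])


def classify_location(
    interval: tuple[int, int], regions: RegionSet
) -> tuple[str, str]:
    """Classify an interval against a RegionSet.

    Returns ``(location_class, region_name)`` where the class is a single
    category when the interval is contained in one, a hyphenated pair such as
    ``"CDS-IGS"`` when it touches exactly two, and ``"mixed"`` for three or
    more.  The region name is that of the category member with the largest
    overlap (names joined with ``"; "`` for hyphenated classes).
    """
    s, e = interval
    n = regions.genome_length
    if not (0 <= s < e <= n):
        raise CoordinateError(f"interval ({s},{e}) outside genome of {n} bp")
    touched: dict[str, tuple[int, str]] = {}
    for name, cat, ivs in regions.regions:
        ov = sum(max(0, min(e, e2) - max(s, s2)) for s2, e2 in ivs)
        if ov > 0 and ov > touched.get(cat, (0, ""))[0]:
            touched[cat] = (ov, name)
    cats = [c for c in CATEGORY_ORDER if c in touched]
    if not cats:
        return "other", ""
    if len(cats) == 1:
        return cats[0], touched[cats[0]][1]
    if len(cats) == 2:
        return "-".join(cats), "; ".join(touched[c][1] for c in cats)
    return "mixed", "; ".join(touched[c][1] for c in cats)
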