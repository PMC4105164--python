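"""Quadripartite (LSC / IRb / SSC / IRa) structure detection.

The inverted-repeat pair is found as the maximal-length pair of disjoint,
exactly reverse-complementary segments on the circle.  Detection is seeded
with exact k-mer matches (k=25) between the doubled sequence and its reverse
complement, grouped by diagonal and extended maximally, so it is deterministic
and checkable against a brute-force all-substring scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._dna import encode, revcomp
from .genome_io import Feature, PlastomeRecord

SEED_K = 25


class NoQuadripartiteError(ValueError):
    """No inverted-repeat pair of the required size exists."""


class AmbiguousStructureError(ValueError):
    """More than one maximal candidate IR pair (or LSC == SSC)."""


@dataclass
class QuadripartitePartition:
    """The four region intervals and junctions, in genome coordinates.

    Intervals are (start, end) 0-based half-open and may wrap the origin
    (start > end means the region runs through position 0).  Junction
    coordinates are the first base of the downstream region: JLB = first base
    of IRb, JSB = first base of SSC, JSA = first base of IRa, JLA = first base
    of LSC.
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    genome_length: int

    @property
    def lsc_length(self) -> int:
        return self._arclen(self.lsc)

    @property
    def ssc_length(self) -> int:
        return self._arclen(self.ssc)

    @property
    def ir_length(self) -> int:
        return self._arclen(self.irb)

    def _arclen(self, iv: tuple[int, int]) -> int:
        s, e = iv
        return e - s if e > s else self.genome_length - s + e

    @property
    def junctions(self) -> dict[str, int]:
        return {
            "JLB": self.irb[0],
            "JSB": self.ssc[0],
            "JSA": self.ira[0],
            "JLA": self.lsc[0],
        }


@dataclass
class JunctionReport:
    """Signed gene-to-junction distances and gene/IR overlaps (Fig.-2 style)."""

    rows: list[dict] = field(default_factory=list)
    convention: str = (
        "distance = minimal circular distance from the gene end nearest the "
        "junction; negative when the gene span covers the junction"
    )


def _maximal_inverted_matches(seq: str, min_len: int) -> list[tuple[int, int, int]]:
    """All maximal exact inverted matches ≥ min_len on the circle.

    Returns (i, j, L): circular segment starting at i of length L equals the
    reverse complement of the circular segment starting at j of length L.
    """
    n = len(seq)
    d = seq + seq
    rd = revcomp(d)
    k = min(SEED_K, max(4, n // 4))
    a = encode(d)
    b = encode(rd)
    # rolling k-mer codes (base-5 to keep N distinct)
    mult = 5 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    def codes(x: np.ndarray) -> np.ndarray:
        m = np.lib.stride_tricks.sliding_window_view(x, k).astype(np.int64)
        return m @ mult

    ca, cb = codes(a), codes(b)
    order_a = np.argsort(ca, kind="stable")
    order_b = np.argsort(cb, kind="stable")
    sa, sb = ca[order_a], cb[order_b]
    # join equal codes
    pairs: list[tuple[int, int]] = []
    ia = ib = 0
    while ia < len(sa) and ib < len(sb):
        if sa[ia] < sb[ib]:
            ia += 1
        elif sa[ia] > sb[ib]:
            ib += 1
        else:
            v = sa[ia]
            ja = ia
            while ja < len(sa) and sa[ja] == v:
                ja += 1
            jb = ib
            while jb < len(sb) and sb[jb] == v:
                jb += 1
            for pa in order_a[ia:ja]:
                for pb in order_b[ib:jb]:
                    pairs.append((int(pa), int(pb)))
            ia, ib = ja, jb
    # group by diagonal, take maximal runs, extend by direct comparison
    by_diag: dict[int, list[int]] = {}
    for pa, pb in pairs:
        by_diag.setdefault(pa - pb, []).append(pa)
    out = set()
    for diag, positions in by_diag.items():
        positions.sort()
        run_start = positions[0]
        prev = positions[0]
        runs = []
        for p in positions[1:]:
            if p != prev + 1:     # seeds of one exact match are consecutive
                runs.append((run_start, prev))
                run_start = p
            prev = p
        runs.append((run_start, prev))
        for rs, re_ in runs:
            # extend the guaranteed-exact span [rs, re_+k) along the diagonal
            lo, hi = rs, re_ + k
            while lo > 0 and lo - 1 - diag >= 0 and d[lo - 1] == rd[lo - 1 - diag]:
                lo -= 1
            while hi < 2 * n and 0 <= hi - diag < 2 * n and d[hi] == rd[hi - diag]:
                hi += 1
            L = min(hi - lo, n)
            i = lo % n
            j = (2 * n - (lo - diag) - L) % n
            out.add((i, j, L))
    return list(out)


def _disjoint_on_circle(i: int, j: int, L: int, n: int) -> bool:
    """True if circular intervals [i,i+L) and [j,j+L) do not overlap."""
    if 2 * L > n:
        return False
    gap1 = (j - (i + L)) % n
    gap2 = (i - (j + L)) % n
    return gap1 + gap2 == n - 2 * L and (j - i) % n >= L and (i - j) % n >= L


def detect_quadripartite(
    record: PlastomeRecord, min_ir: int = 10000
) -> QuadripartitePartition:
    """Detect the LSC/IRb/SSC/IRa partition of a circular plastome.

    The longer single-copy arc is named LSC; IRb is the IR copy reached first
    when walking forward from the end of the LSC.
    """
    seq = record.sequence
    n = len(seq)
    if n <= 2 * min_ir:
        raise NoQuadripartiteError(
            f"{record.id}: genome ({n} bp) too short for min_ir={min_ir}"
        )
    cands = []
    for i, j, L in _maximal_inverted_matches(seq, min_ir):
        if L >= min_ir and _disjoint_on_circle(i, j, L, n):
            key = tuple(sorted([(i, L), (j, L)]))
            cands.append((L, key, (i, j, L)))
    if not cands:
        raise NoQuadripartiteError(
            f"{record.id}: no quadripartite structure (no inverted repeat "
            f">= {min_ir} bp)"
        )
    best_len = max(c[0] for c in cands)
    best = {c[1]: c[2] for c in cands if c[0] == best_len}
    if len(best) > 1:
        raise AmbiguousStructureError(
            f"{record.id}: {len(best)} equal maximal IR candidates: "
            f"{sorted(best)}"
        )
    i, j, L = next(iter(best.values()))
    # the two single-copy arcs between the IR copies
    arc1 = ((i + L) % n, j)               # from end of copy1 to start of copy2
    arc2 = ((j + L) % n, i)
    len1 = (arc1[1] - arc1[0]) % n
    len2 = (arc2[1] - arc2[0]) % n
    if len1 == len2:
        raise AmbiguousStructureError(f"{record.id}: LSC and SSC equal length")
    if len1 > len2:
        lsc, ssc = arc1, arc2
        irb = (j % n, (j + L) % n)        # first IR after LSC end
        ira = (i % n, (i + L) % n)
    else:
        lsc, ssc = arc2, arc1
        irb = (i % n, (i + L) % n)
        ira = (j % n, (j + L) % n)
    part = QuadripartitePartition(
        lsc=lsc, irb=irb, ssc=ssc, ira=ira, genome_length=n
    )
    assert part.lsc_length + part.ssc_length + 2 * part.ir_length == n
    assert part.lsc_length > part.ssc_length
    # the two IR copies must be exactly reverse-complementary
    assert _circular_slice(seq, *part.irb) == revcomp(_circular_slice(seq, *part.ira))
    return part


def _circular_slice(seq: str, s: int, e: int) -> str:
    return seq[s:e] if e > s else seq[s:] + seq[:e]


def canonical_orientation(
    record: PlastomeRecord, partition: QuadripartitePartition
) -> tuple[PlastomeRecord, QuadripartitePartition]:
    """Rotate/flip so position 0 is the first LSC base and order is
    LSC, IRb, SSC, IRa along the forward strand.

    Of the two orientations satisfying that order (the detected one and the
    reverse complement re-detected), the one whose sequence is
    lexicographically smaller is chosen, making the canonical form invariant
    to rotation and to reverse-complementation of the input.
    """
    fwd = _rotate_record(record, partition.lsc[0])
    rc_rec = _revcomp_record(record)
    rc_part = detect_quadripartite(rc_rec, min_ir=partition.ir_length)
    rev = _rotate_record(rc_rec, rc_part.lsc[0])
    chosen = fwd if fwd.sequence <= rev.sequence else rev
    part = detect_quadripartite(chosen, min_ir=partition.ir_length)
    return chosen, part


def _rotate_record(record: PlastomeRecord, shift: int) -> PlastomeRecord:
    n = len(record.sequence)
    seq = record.sequence[shift:] + record.sequence[:shift]
    feats = []
    for f in record.features:
        ivs = []
        for s, e, strand in f.intervals:
            s2, e2 = (s - shift) % n, (e - shift) % n
            if e2 == 0:
                e2 = n
            if s2 < e2:
                ivs.append((s2, e2, strand))
            else:                       # interval now wraps the origin
                ivs.append((s2, n, strand))
                ivs.append((0, e2, strand))
        feats.append(Feature(f.name, f.kind, ivs, f.copy_tag))
    return PlastomeRecord(record.id, seq, record.circular, feats, record.source)


def _revcomp_record(record: PlastomeRecord) -> PlastomeRecord:
    n = len(record.sequence)
    seq = revcomp(record.sequence)
    flip = {"+": "-", "-": "+"}
    feats = [
        Feature(
            f.name,
            f.kind,
            sorted((n - e, n - s, flip[strand]) for s, e, strand in f.intervals),
            f.copy_tag,
        )
        for f in record.features
    ]
    return PlastomeRecord(record.id, seq, record.circular, feats, record.source)


def junction_report(
    record: PlastomeRecord,
    partition: QuadripartitePartition,
    genes: tuple[str, ...] = ("ndhF", "ycf1", "rps19"),
) -> JunctionReport:
    """Distances from named genes to the four junctions, plus IR overlaps."""
    import logging

    n = partition.genome_length
    report = JunctionReport()
    juncs = partition.junctions
    found = {g.name for g in record.genes()}
    for name in genes:
        if name not in found:
            logging.getLogger(__name__).warning(
                "%s: gene %r not annotated; omitted from junction report",
                record.id, name,
            )
            continue
        for feat in record.genes():
            if feat.name != name:
                continue
            row: dict = {"gene": name, "copy_tag": feat.copy_tag}
            gs, ge = feat.start, feat.end
            for jname, j in juncs.items():
                d_start = min((gs - j) % n, (j - gs) % n)
                d_end = min((ge - j) % n, (j - ge) % n)
                dist = min(d_start, d_end)
                if _covers(gs, ge, j, n):
                    dist = -dist if dist else 0
                row[jname] = dist
            row["ir_a_overlap"] = _overlap_circular((gs, ge), partition.ira, n)
            row["ir_b_overlap"] = _overlap_circular((gs, ge), partition.irb, n)
            report.rows.append(row)
    return report


def _covers(gs: int, ge: int, j: int, n: int) -> bool:
    """Does the (non-wrapping) gene span [gs, ge) strictly contain junction j?"""
    return gs < j < ge


def _overlap_circular(a: tuple[int, int], b: tuple[int, int], n: int) -> int:
    def unroll(iv):
        s, e = iv
        return [(s, e)] if e > s else [(s, n), (0, e)]

    total = 0
    for s1, e1 in unroll(a):
        for s2, e2 in unroll(b):
            total += max(0, min(e1, e2) - max(s1, s2))
    return total
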